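"""Trajectory container, structure I/O and atom selection.

Conventions
-----------
* All internal coordinates are angstroms (A).  GRO input, which is in nm,
  is scaled by exactly 10 on read and back on write.
* Residue indices are kept 1-based exactly as printed in the PDB/GRO file.
* Times are nanoseconds.  PDB and GRO files carry no time axis, so
  :func:`read_structure` accepts a ``dt`` between stored frames (default 1).
* Backbone atoms are N, CA, C, O plus the amide hydrogen (H/HN) and the
  terminal OXT.  Side-chain heavy atoms are all non-hydrogen atoms outside
  that set; for glycine the CA doubles as the side-chain center so that
  per-residue side-chain centers of mass are always defined.

File parsing and writing are delegated to MDAnalysis; the classes here are
a deliberately small, NumPy-backed container layer that the analysis
modules share.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._constants import ELEMENT_MASSES

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "read_structure",
    "write_structure",
    "select_atoms",
    "load_nonbonded_params",
    "infer_element",
    "default_mass",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "HN", "OXT"})


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name.

    Digits and primes are stripped; a leading digit (``1HB``) marks a
    hydrogen.  Two-letter element names (FE, ZN, ...) are recognised when
    the whole stripped name matches; otherwise the first letter is used,
    so CA is carbon-alpha, not calcium.
    """
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        return "H"
    stripped = re.sub(r"[0-9'*]", "", name).upper()
    if stripped in ELEMENT_MASSES and len(stripped) == 2 and stripped not in ("CA",):
        return stripped
    first = stripped[:1]
    if first in ELEMENT_MASSES:
        return first
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def default_mass(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no default mass for element {element!r}") from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``charge`` (e), ``lj_sigma`` (A) and ``lj_epsilon`` (kcal/mol) are
    optional non-bonded parameters, typically supplied via a TSV sidecar
    (:func:`load_nonbonded_params`).
    """

    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    element: str = ""
    mass: float = 0.0
    charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    is_backbone: bool = field(default=False)
    is_sidechain_heavy: bool = field(default=False)

    def __post_init__(self):
        if not self.element:
            object.__setattr__(self, "element", infer_element(self.atom_name))
        if self.mass <= 0.0:
            object.__setattr__(self, "mass", default_mass(self.element))
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        name = self.atom_name.strip().upper()
        backbone = name in BACKBONE_NAMES
        sidechain_heavy = self.element != "H" and name not in BACKBONE_NAMES
        if self.residue_name.strip().upper() == "GLY" and name == "CA":
            # glycine has no side chain; its CA serves as the side-chain center
            sidechain_heavy = True
        object.__setattr__(self, "is_backbone", backbone)
        object.__setattr__(self, "is_sidechain_heavy", sidechain_heavy)


@dataclass
class Frame:
    """A single snapshot: time (ns), coordinates (n_atoms, 3) in A."""

    time: float
    coords: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: list[AtomRecord]
    frames: list[Frame]

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a Trajectory needs at least one frame")
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coords.shape[0]} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        """Time step between stored frames (ns); 0 for single-frame."""
        if len(self.frames) < 2:
            return 0.0
        return self.frames[1].time - self.frames[0].time

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.topology:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain_atom_indices(self, chain_id: str) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.topology) if a.chain_id == chain_id],
            dtype=int,
        )

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.topology:
            seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)

    def residue_atom_indices(self, chain_id: str, residue_index: int) -> np.ndarray:
        return np.array(
            [
                i
                for i, a in enumerate(self.topology)
                if a.chain_id == chain_id and a.residue_index == residue_index
            ],
            dtype=int,
        )

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])


# ---------------------------------------------------------------------------
# structure I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure format {fmt!r} (use pdb or gro)")
    return fmt


def read_structure(path: str | Path, fmt: str | None = None, dt: float = 1.0) -> Trajectory:
    """Read a (multi-MODEL) PDB or a GRO file into a :class:`Trajectory`.

    GRO coordinates (nm) are converted to A.  ``dt`` assigns times
    ``i * dt`` ns to the stored frames, since neither format carries time.
    """
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt.upper(), to_guess=())
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"failed to parse {fmt.upper()} file {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise ValueError(f"no atoms found in {path}")

    names = [str(n) for n in u.atoms.names]
    resnames = [str(r) for r in u.atoms.resnames]
    resids = [int(r) for r in u.atoms.resids]
    if hasattr(u.atoms, "chainIDs"):
        chains = [str(c).strip() or "A" for c in u.atoms.chainIDs]
    elif hasattr(u.atoms, "segids"):
        chains = [str(c).strip() or "A" for c in u.atoms.segids]
    else:
        chains = ["A"] * len(u.atoms)

    topology = [
        AtomRecord(atom_name=n, residue_name=rn, residue_index=ri, chain_id=c)
        for n, rn, ri, c in zip(names, resnames, resids, chains)
    ]

    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            box = None
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                box = np.array(ts.dimensions[:3], dtype=float)
            frames.append(
                Frame(time=i * dt, coords=u.atoms.positions.astype(float), box=box)
            )
    return Trajectory(topology=topology, frames=frames)


def write_structure(traj: Trajectory, path: str | Path, fmt: str | None = None) -> None:
    """Write a trajectory as multi-MODEL PDB or (single-frame) GRO.

    Round-tripping through PDB preserves coordinates to the format's
    0.001 A precision.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    fmt = _infer_format(path, fmt)
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    if fmt == "gro" and traj.n_frames > 1:
        raise ValueError("GRO holds a single frame; use PDB for multi-frame output")

    # group consecutive atoms into residues / segments
    res_index = []
    res_keys: list[tuple[str, int, str]] = []
    for a in traj.topology:
        key = (a.chain_id, a.residue_index, a.residue_name)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        res_index.append(len(res_keys) - 1)
    seg_ids: list[str] = []
    res_segindex = []
    for chain, _, _ in res_keys:
        if chain not in seg_ids:
            seg_ids.append(chain)
        res_segindex.append(seg_ids.index(chain))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=traj.n_atoms,
            n_residues=len(res_keys),
            n_segments=len(seg_ids),
            atom_resindex=np.array(res_index),
            residue_segindex=np.array(res_segindex),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in traj.topology])
        u.add_TopologyAttr("elements", [a.element for a in traj.topology])
        u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in traj.topology])
        u.add_TopologyAttr("segids", seg_ids)
        coords = np.stack([f.coords for f in traj.frames]).astype(np.float32)
        u.load_new(coords, format=MemoryReader, order="fac")
        with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=(fmt == "pdb")) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def load_nonbonded_params(traj: Trajectory, path: str | Path) -> Trajectory:
    """Attach charges and Lennard-Jones parameters from a TSV sidecar.

    Expected columns: ``atom_index`` (0-based index into the topology),
    ``charge`` (e), ``sigma_A`` (A), ``epsilon_kcal`` (kcal/mol).
    Returns a new Trajectory sharing the frames.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"atom_index", "charge", "sigma_A", "epsilon_kcal"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sidecar {path} missing columns: {sorted(missing)}")
    topo = list(traj.topology)
    for row in table.itertuples(index=False):
        i = int(row.atom_index)
        if not 0 <= i < len(topo):
            raise IndexError(f"sidecar atom_index {i} out of range")
        topo[i] = replace(
            topo[i],
            charge=float(row.charge),
            lj_sigma=float(row.sigma_A),
            lj_epsilon=float(row.epsilon_kcal),
        )
    return Trajectory(topology=topo, frames=traj.frames)


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelectionParser:
    """Recursive-descent parser for a small selection grammar.

    expr     := term ('or' term)*
    term     := factor ('and' factor)*
    factor   := 'not' factor | '(' expr ')' | primitive
    primitive:= 'chain' ID | 'resid' N[-M | :M] | 'name' A[,B,...]
               | 'backbone' | 'sidechain' | 'all'
    """

    def __init__(self, tokens: list[str], topology: Sequence[AtomRecord]):
        self.tokens = tokens
        self.pos = 0
        self.topology = topology
        self.universe = frozenset(range(len(topology)))

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> frozenset[int]:
        result = self.expr()
        if self.peek() is not None:
            raise ValueError(f"unexpected token {self.peek()!r} in selection")
        return result

    def expr(self) -> frozenset[int]:
        out = self.term()
        while self.peek() == "or":
            self.take()
            out = out | self.term()
        return out

    def term(self) -> frozenset[int]:
        out = self.factor()
        while self.peek() == "and":
            self.take()
            out = out & self.factor()
        return out

    def factor(self) -> frozenset[int]:
        tok = self.peek()
        if tok == "not":
            self.take()
            return self.universe - self.factor()
        if tok == "(":
            self.take()
            inner = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return inner
        return self.primitive()

    def primitive(self) -> frozenset[int]:
        tok = self.take().lower()
        topo = self.topology
        if tok == "all":
            return self.universe
        if tok == "backbone":
            return frozenset(i for i, a in enumerate(topo) if a.is_backbone)
        if tok == "sidechain":
            return frozenset(i for i, a in enumerate(topo) if a.is_sidechain_heavy)
        if tok == "chain":
            cid = self.take()
            return frozenset(i for i, a in enumerate(topo) if a.chain_id == cid)
        if tok == "name":
            names = {n.upper() for n in self.take().split(",") if n}
            return frozenset(
                i for i, a in enumerate(topo) if a.atom_name.upper() in names
            )
        if tok == "resid":
            spec = self.take()
            m = re.fullmatch(r"(\d+)(?:[-:](\d+))?", spec)
            if not m:
                raise ValueError(f"bad resid range {spec!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            return frozenset(
                i for i, a in enumerate(topo) if lo <= a.residue_index <= hi
            )
        raise ValueError(f"unknown selection keyword {tok!r}")


def select_atoms(traj: Trajectory | Sequence[AtomRecord], spec: str) -> list[int]:
    """Evaluate a selection expression; returns sorted unique atom indices.

    Supported predicates: ``chain X``, ``resid N`` / ``resid N-M``,
    ``name CA`` (comma lists allowed), ``backbone``, ``sidechain``,
    ``all``, combined with ``and``/``or``/``not`` and parentheses.
    """
    topology = traj.topology if isinstance(traj, Trajectory) else list(traj)
    tokens = _TOKEN_RE.findall(spec)
    if not tokens:
        raise ValueError("empty selection expression")
    return sorted(_SelectionParser(tokens, topology).parse())
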