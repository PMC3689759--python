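"""Nematic order parameter, fibril-state classification and first-passage times.

The nematic order parameter P2 of a set of molecular unit vectors z_i is
the largest eigenvalue of the ordering tensor

    Q = (1 / 2N) * sum_i (3 z_i z_i^T - I),

which is 1 for perfect (parallel or antiparallel) alignment and small for
disordered arrangements.  For exactly two vectors the closed form
P2 = (1 + 3|cos theta|) / 4 holds, which the tests use as an oracle.

A dimer frame is in the fibril (two-strand beta-sheet) state when P2 is
at or above a threshold (default 0.9) and at least two inter-chain
backbone-backbone hydrogen bonds are present.  The fibril-formation time
is the first passage of that criterion, optionally requiring a run of
consecutive positive frames.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import HBParams, backbone_hb_count
from .core import AtomRecord, Frame, Trajectory

__all__ = [
    "VectorSpec",
    "FibrilCriterion",
    "OrderSeries",
    "molecular_vectors",
    "nematic_p2",
    "end_to_end_cos",
    "classify_fibril",
    "first_passage",
    "order_series",
    "mean_fibril_time",
]


@dataclass(frozen=True)
class VectorSpec:
    """How molecular vectors are built from a chain."""

    mode: str = "end_to_end"  # or "per_residue_backbone"
    atom_name: str = "CA"

    def __post_init__(self):
        if self.mode not in ("end_to_end", "per_residue_backbone"):
            raise ValueError(f"unknown vector mode {self.mode!r}")


@dataclass(frozen=True)
class FibrilCriterion:
    """Fibril-state definition: order threshold plus backbone H-bond count."""

    p2_threshold: float = 0.9
    min_backbone_hb: int = 2
    persistence: int = 1

    def __post_init__(self):
        if not 0 < self.p2_threshold <= 1:
            raise ValueError("p2_threshold must be in (0, 1]")
        if self.min_backbone_hb < 0:
            raise ValueError("min_backbone_hb must be >= 0")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class OrderSeries:
    """Per-frame order diagnostics of a dimer trajectory."""

    time: np.ndarray
    p2: np.ndarray
    cos_theta: np.ndarray
    n_backbone_hb: np.ndarray
    is_fibril: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.p2 = np.asarray(self.p2, dtype=float)
        self.cos_theta = np.asarray(self.cos_theta, dtype=float)
        self.n_backbone_hb = np.asarray(self.n_backbone_hb, dtype=int)
        self.is_fibril = np.asarray(self.is_fibril, dtype=bool)
        n = len(self.time)
        for arr in (self.p2, self.cos_theta, self.n_backbone_hb, self.is_fibril):
            if len(arr) != n:
                raise ValueError("OrderSeries arrays must share one length")
        if np.any(self.p2 < -1e-9) or np.any(self.p2 > 1 + 1e-9):
            raise ValueError("p2 out of [0, 1]")
        if np.any(np.abs(self.cos_theta) > 1 + 1e-9):
            raise ValueError("cos_theta out of [-1, 1]")
        if np.any(self.n_backbone_hb < 0):
            raise ValueError("negative H-bond count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.time,
                "p2": self.p2,
                "cos_theta": self.cos_theta,
                "n_bb_hb": self.n_backbone_hb,
                "is_fibril": self.is_fibril.astype(int),
            }
        )


def _chain_atoms(
    topology: Sequence[AtomRecord], atom_name: str
) -> dict[str, list[int]]:
    chains: dict[str, list[int]] = {}
    for i, a in enumerate(topology):
        if a.atom_name.upper() == atom_name.upper():
            chains.setdefault(a.chain_id, []).append(i)
    return chains


def molecular_vectors(
    frame: Frame, topology: Sequence[AtomRecord], spec: VectorSpec | None = None
) -> np.ndarray:
    """Unit molecular vectors for each chain (or each residue segment).

    ``end_to_end``: one vector per chain, first to last matching atom.
    ``per_residue_backbone``: one vector per residue from its CA to the
    next residue's CA within the same chain.
    """
    spec = spec or VectorSpec()
    chains = _chain_atoms(topology, spec.atom_name)
    vectors = []
    for cid, idx in chains.items():
        if len(idx) < 2:
            raise ValueError(
                f"chain {cid!r} has fewer than 2 atoms named {spec.atom_name!r}"
            )
        if spec.mode == "end_to_end":
            v = frame.coords[idx[-1]] - frame.coords[idx[0]]
            vectors.append(v)
        else:
            for a, b in zip(idx, idx[1:]):
                vectors.append(frame.coords[b] - frame.coords[a])
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length molecular vector")
    return vectors / norms[:, None]


def nematic_p2(vectors: np.ndarray) -> float:
    """Largest eigenvalue of the ordering tensor Q; in [0, 1].

    Invariant under global rotation and under flipping any vector's sign.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("need at least two 3-vectors")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length input vector")
    v = v / norms[:, None]
    n = v.shape[0]
    q = (3.0 * v.T @ v - n * np.eye(3)) / (2.0 * n)
    eig = np.linalg.eigvalsh(q)
    return float(np.clip(eig[-1], 0.0, 1.0))


def end_to_end_cos(
    frame: Frame, topology: Sequence[AtomRecord], atom_name: str = "CA"
) -> float:
    """Cosine of the angle between the two chains' end-to-end vectors."""
    chains = _chain_atoms(topology, atom_name)
    if len(chains) != 2:
        raise ValueError(f"need exactly two chains, found {len(chains)}")
    units = []
    for cid, idx in chains.items():
        if len(idx) < 2:
            raise ValueError(f"chain {cid!r} has fewer than 2 atoms named {atom_name!r}")
        v = frame.coords[idx[-1]] - frame.coords[idx[0]]
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero-length end-to-end vector")
        units.append(v / n)
    return float(np.clip(np.dot(units[0], units[1]), -1.0, 1.0))


def classify_fibril(
    p2: float, n_backbone_hb: int, criterion: FibrilCriterion | None = None
) -> bool:
    """True iff p2 >= threshold and the backbone H-bond count is sufficient."""
    criterion = criterion or FibrilCriterion()
    return bool(p2 >= criterion.p2_threshold and n_backbone_hb >= criterion.min_backbone_hb)


def first_passage(
    series: OrderSeries, criterion: FibrilCriterion | None = None
) -> float | None:
    """Time (ns) of the first frame starting a run of >= ``persistence``
    consecutive fibril-positive frames; None if the criterion is never met.

    Flags are re-evaluated from the stored p2 and H-bond counts so that
    alternative criteria can be probed on one series.
    """
    criterion = criterion or FibrilCriterion()
    flags = (series.p2 >= criterion.p2_threshold) & (
        series.n_backbone_hb >= criterion.min_backbone_hb
    )
    run = 0
    for i, ok in enumerate(flags):
        run = run + 1 if ok else 0
        if run >= criterion.persistence:
            return float(series.time[i - criterion.persistence + 1])
    return None


def order_series(
    traj: Trajectory,
    spec: VectorSpec | None = None,
    criterion: FibrilCriterion | None = None,
    hb_params: HBParams | None = None,
) -> OrderSeries:
    """Per-frame P2, end-to-end cos theta, backbone H-bonds and fibril flag."""
    spec = spec or VectorSpec()
    criterion = criterion or FibrilCriterion()
    if len(traj.chain_ids()) != 2:
        raise ValueError("order_series requires a two-chain trajectory")
    times, p2s, coss, hbs, flags = [], [], [], [], []
    for frame in traj.frames:
        vecs = molecular_vectors(frame, traj.topology, spec)
        p2 = nematic_p2(vecs)
        cos = end_to_end_cos(frame, traj.topology, spec.atom_name)
        nhb = backbone_hb_count(frame, traj.topology, hb_params)
        times.append(frame.time)
        p2s.append(p2)
        coss.append(cos)
        hbs.append(nhb)
        flags.append(classify_fibril(p2, nhb, criterion))
    return OrderSeries(
        time=np.array(times),
        p2=np.array(p2s),
        cos_theta=np.array(coss),
        n_backbone_hb=np.array(hbs),
        is_fibril=np.array(flags),
    )


def mean_fibril_time(times: Sequence[float]) -> float:
    """Arithmetic mean first-passage time over independent runs (ns)."""
    arr = [t for t in times if t is not None]
    if not arr:
        raise ValueError("no fibril-forming runs to average")
    return float(np.mean(arr))
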