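"""Synthetic trajectories and energy/secondary-structure streams.

The dimer generator emulates, with scripted (not emergent) kinetics, what
an all-atom MD run of two short amyloidogenic peptides shows: an initial
disordered phase in which the chains tumble independently far apart,
followed from a prescribed frame onward by an ordered two-strand
beta-sheet.  Each residue carries a minimal atom set (N, amide H, CA, a
CB side-chain pseudo-atom, C, O); the ordered phase places the strands as
idealized extended beta geometry (Ca-Ca 3.5 A along the strand, 4.8 A
between strands) with N-H...O=C pairs that satisfy the default geometric
hydrogen-bond criterion, so the fibril classification in
:mod:`oligotraj.order` has an exact ground truth.

Gaussian component streams and per-residue secondary-structure letter
streams with known probabilities are generated the same way: fully
reproducible from an explicit seed, with moments that converge at the
central-limit rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._constants import AA_THREE, RESIDUE_MASSES
from .core import AtomRecord, Frame, Trajectory
from .energetics import COMPONENT_FIELDS, EnergyComponentsRecord

__all__ = [
    "DimerScenario",
    "ComponentStreamSpec",
    "generate_dimer_trajectory",
    "generate_component_stream",
    "generate_ss_stream",
]

# idealized extended-strand internal coordinates (A)
_RESIDUE_SPACING = 3.5          # Ca-Ca repeat along the strand
_STRAND_SEPARATION = 4.8        # backbone-line separation between strands
_BACKBONE_OFFSET = 0.335        # N/C protrusion toward the facing strand
_NH_LENGTH = 1.0
_CO_LENGTH = 1.23
_CB_DROP = 1.5                  # side-chain pseudo-atom below the strand plane
_CHAIN_GAP = 40.0               # centroid separation in the disordered phase
_BACKBONE_MASS = 55.04          # N + H + CA + C + O


@dataclass(frozen=True)
class DimerScenario:
    """Ground-truth description of one scripted dimer trajectory."""

    sequence: str = "LVEALYL"
    n_residues_per_chain: int | None = None
    n_frames: int = 100
    dt: float = 0.1
    transition_frame: int = 50
    orientation: str = "antiparallel"
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        n = len(self.sequence)
        if self.n_residues_per_chain is None:
            object.__setattr__(self, "n_residues_per_chain", n)
        elif self.n_residues_per_chain != n:
            raise ValueError("n_residues_per_chain must match the sequence length")
        if n < 2:
            raise ValueError("need at least two residues per chain")
        if not 0 <= self.transition_frame <= self.n_frames:
            raise ValueError("transition_frame out of range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.orientation not in ("antiparallel", "parallel"):
            raise ValueError("orientation must be antiparallel or parallel")
        for aa in self.sequence:
            if aa.upper() not in AA_THREE:
                raise ValueError(f"unknown amino acid {aa!r}")


@dataclass(frozen=True)
class ComponentStreamSpec:
    """Gaussian per-snapshot MM-PBSA component stream."""

    means: tuple[float, float, float, float, float]
    sds: tuple[float, float, float, float, float] = (0.0,) * 5
    n_snapshots: int = 100
    seed: int = 0

    def __post_init__(self):
        if len(self.means) != 5 or len(self.sds) != 5:
            raise ValueError("means and sds must have five entries (elec, vdw, sur, pb, tds)")
        if any(s < 0 for s in self.sds):
            raise ValueError("sds must be non-negative")
        if self.n_snapshots < 1:
            raise ValueError("n_snapshots must be >= 1")


_ATOM_ORDER = ("N", "H", "CA", "CB", "C", "O")


def _chain_topology(sequence: str, chain_id: str) -> list[AtomRecord]:
    atoms = []
    for i, aa in enumerate(sequence.upper(), start=1):
        resname = AA_THREE[aa]
        cb_mass = max(RESIDUE_MASSES[resname] - _BACKBONE_MASS, 12.011)
        for name in _ATOM_ORDER:
            if name == "CB" and resname == "GLY":
                continue
            atoms.append(
                AtomRecord(
                    atom_name=name,
                    residue_name=resname,
                    residue_index=i,
                    chain_id=chain_id,
                    mass=cb_mass if name == "CB" else 0.0,
                )
            )
    return atoms


def _strand_template(n_res: int, has_cb: Sequence[bool], flip_parity: bool) -> np.ndarray:
    """Template strand along +x at y = 0, facing alternate sides in y."""
    coords = []
    for i in range(n_res):
        s = 1.0 if (i % 2 == 0) != flip_parity else -1.0
        x = i * _RESIDUE_SPACING
        atoms = {
            "N": (x - 1.2, s * _BACKBONE_OFFSET, 0.0),
            "H": (x - 1.2, s * (_BACKBONE_OFFSET + _NH_LENGTH), 0.0),
            "CA": (x, 0.0, 0.0),
            "CB": (x, 0.0, -_CB_DROP),
            "C": (x + 1.2, s * _BACKBONE_OFFSET, 0.0),
            "O": (x + 1.2, s * (_BACKBONE_OFFSET + _CO_LENGTH), 0.0),
        }
        for name in _ATOM_ORDER:
            if name == "CB" and not has_cb[i]:
                continue
            coords.append(atoms[name])
    return np.asarray(coords)


def _ordered_coords(scenario: DimerScenario) -> np.ndarray:
    """Noise-free coordinates of the ordered two-strand beta arrangement."""
    n = scenario.n_residues_per_chain
    has_cb = [AA_THREE[aa.upper()] != "GLY" for aa in scenario.sequence]
    chain_a = _strand_template(n, has_cb, flip_parity=False)
    x0 = (n - 1) * _RESIDUE_SPACING
    if scenario.orientation == "antiparallel":
        chain_b = _strand_template(n, has_cb, flip_parity=False)
        chain_b = chain_b * np.array([-1.0, -1.0, 1.0]) + np.array(
            [x0, _STRAND_SEPARATION, 0.0]
        )
    else:
        chain_b = _strand_template(n, has_cb, flip_parity=True)
        chain_b = chain_b * np.array([1.0, -1.0, 1.0]) + np.array(
            [1.1, _STRAND_SEPARATION, 0.0]
        )
    return np.vstack([chain_a, chain_b])


def generate_dimer_trajectory(scenario: DimerScenario) -> Trajectory:
    """Scripted disordered-to-beta-sheet dimer trajectory.

    Frames before ``transition_frame`` rotate each chain rigidly by a
    uniform random rotation about its centroid, with centroids 40 A apart
    so no inter-chain hydrogen bonds can form.  Frames at and after the
    transition use the ordered strand arrangement with the requested
    mutual orientation.  Gaussian positional noise of ``noise_sigma`` (A)
    is added to every frame.  Bit-reproducible from ``seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    topo = _chain_topology(scenario.sequence, "A") + _chain_topology(
        scenario.sequence, "B"
    )
    ordered = _ordered_coords(scenario)
    n_a = sum(1 for a in topo if a.chain_id == "A")
    chain_a_tpl = ordered[:n_a]
    chain_b_tpl = ordered[n_a:]

    frames = []
    for i in range(scenario.n_frames):
        if i < scenario.transition_frame:
            coords = np.empty_like(ordered)
            for tpl, sl, center in (
                (chain_a_tpl, slice(0, n_a), np.zeros(3)),
                (chain_b_tpl, slice(n_a, None), np.array([_CHAIN_GAP, 0.0, 0.0])),
            ):
                rot = Rotation.random(rng=rng)
                centered = tpl - tpl.mean(axis=0)
                coords[sl] = rot.apply(centered) + center
        else:
            coords = ordered.copy()
        if scenario.noise_sigma > 0:
            coords = coords + rng.normal(0.0, scenario.noise_sigma, coords.shape)
        frames.append(Frame(time=i * scenario.dt, coords=coords))
    return Trajectory(topology=topo, frames=frames)


def generate_component_stream(spec: ComponentStreamSpec) -> list[EnergyComponentsRecord]:
    """Independent Gaussian draws per component per snapshot."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.normal(
        loc=np.asarray(spec.means), scale=np.asarray(spec.sds), size=(spec.n_snapshots, 5)
    )
    return [
        EnergyComponentsRecord(*row, label=f"snap{i}")
        for i, row in enumerate(draws)
    ]


def generate_ss_stream(
    profile: Sequence[dict[str, float]],
    n_frames: int,
    seed: int = 0,
    residue_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-frame, per-residue secondary-structure letters with known truth.

    ``profile`` gives one dict of letter probabilities per residue; each
    must sum to 1 (tolerance 1e-9).  Returns a DataFrame with one row per
    frame and one column per residue.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    columns = {}
    labels = (
        list(residue_labels)
        if residue_labels is not None
        else [f"res{i + 1}" for i in range(len(profile))]
    )
    if len(labels) != len(profile):
        raise ValueError("residue_labels must match profile length")
    for label, probs in zip(labels, profile):
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities for {label} sum to {total}, not 1")
        letters = list(probs)
        p = np.array([probs[l] for l in letters])
        columns[label] = rng.choice(letters, size=n_frames, p=p)
    return pd.DataFrame(columns)
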