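"""Side-chain contact maps, geometric hydrogen bonds and pair energies.

A side-chain (SC-SC) contact exists when the mass-weighted center of the
two residues' side-chain heavy atoms lies within a cutoff (default 6.5 A,
boundary inclusive); glycine's side-chain center is its CA.  A hydrogen
bond is detected geometrically: donor-acceptor distance <= 3.5 A and
D-H-A angle >= 135 deg by default (both configurable; the angle threshold
is a convention, not a measured constant).  Donor hydrogens are located
geometrically as H atoms within 1.25 A of the donor heavy atom, so no
hydrogen-naming table is needed.

Residue-pair interaction energies are plain unscreened Coulomb plus
Lennard-Jones sums over inter-residue atom pairs with Lorentz-Berthelot
combination; they reproduce residue-residue interaction maps, not an MD
engine's full non-bonded energy (no PME, no exclusions, no 1-4 scaling).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._constants import COULOMB_KCAL_A_E2
from .core import AtomRecord, Frame, Trajectory

__all__ = [
    "HBParams",
    "ContactMap",
    "sc_contact",
    "detect_hbonds",
    "backbone_hb_count",
    "contact_probability_map",
    "residue_pair_energy",
    "energy_map",
]

logger = logging.getLogger(__name__)

#: default donor heavy-atom names (must carry an attached H in the frame)
DEFAULT_DONORS = frozenset(
    {"N", "OG", "OG1", "OH", "NE", "NH1", "NH2", "NE2", "ND1", "ND2", "NZ", "NE1", "SG"}
)
#: default acceptor atom names
DEFAULT_ACCEPTORS = frozenset(
    {"O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH", "ND1", "NE2", "SD"}
)

#: maximum covalent D-H distance used to attach hydrogens to donors (A);
#: generous enough that moderate positional noise does not detach amide H
H_ATTACH_CUTOFF = 1.4


@dataclass(frozen=True)
class HBParams:
    """Geometric hydrogen-bond criterion."""

    da_cutoff: float = 3.5
    dha_min_angle: float = 135.0
    donors: frozenset[str] = DEFAULT_DONORS
    acceptors: frozenset[str] = DEFAULT_ACCEPTORS

    def __post_init__(self):
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not 0 < self.dha_min_angle <= 180:
            raise ValueError("dha_min_angle must be in (0, 180]")


@dataclass
class ContactMap:
    """Residue-pair matrix: probabilities in [0, 1] or energies in kcal/mol."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    kind: str  # {sidechain, hbond, energy}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("contact map shape does not match labels")
        if self.kind in ("sidechain", "hbond"):
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValueError("contact probabilities must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


ResidueKey = tuple[str, int]


def _residue_atoms(topology: Sequence[AtomRecord]) -> dict[ResidueKey, list[int]]:
    out: dict[ResidueKey, list[int]] = {}
    for i, a in enumerate(topology):
        out.setdefault((a.chain_id, a.residue_index), []).append(i)
    return out


def _sidechain_com(
    frame: Frame,
    topology: Sequence[AtomRecord],
    atom_idx: Iterable[int],
    whole_residue: bool = False,
) -> np.ndarray:
    idx = [
        i
        for i in atom_idx
        if (whole_residue and topology[i].element != "H") or topology[i].is_sidechain_heavy
    ]
    if not idx:
        raise ValueError("residue has no heavy atoms for its center of mass")
    w = np.array([topology[i].mass for i in idx])
    return np.average(frame.coords[idx], axis=0, weights=w)


def sc_contact(
    frame: Frame,
    topology: Sequence[AtomRecord],
    res_i: ResidueKey,
    res_j: ResidueKey,
    cutoff: float = 6.5,
    whole_residue: bool = False,
) -> bool:
    """True iff the residues' side-chain centers of mass are within cutoff.

    ``whole_residue=True`` switches to the all-heavy-atom center.
    """
    residues = _residue_atoms(topology)
    for key in (res_i, res_j):
        if key not in residues:
            raise KeyError(f"residue {key} not in topology")
    ci = _sidechain_com(frame, topology, residues[res_i], whole_residue)
    cj = _sidechain_com(frame, topology, residues[res_j], whole_residue)
    return bool(np.linalg.norm(ci - cj) <= cutoff)


def _attached_hydrogens(
    frame: Frame, topology: Sequence[AtomRecord], donor: int
) -> list[int]:
    d = frame.coords[donor]
    out = []
    for i, a in enumerate(topology):
        if a.element == "H" and np.linalg.norm(frame.coords[i] - d) <= H_ATTACH_CUTOFF:
            out.append(i)
    return out


def detect_hbonds(
    frame: Frame,
    topology: Sequence[AtomRecord],
    params: HBParams | None = None,
    group1: Iterable[int] | None = None,
    group2: Iterable[int] | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor, H, acceptor) triplets satisfying the geometric criterion.

    Donors are searched in ``group1`` and acceptors in ``group2`` and vice
    versa.  With no groups given, all atoms are considered and pairs within
    one residue are excluded.  Donors with no attached hydrogen are skipped
    with a logged warning.
    """
    params = params or HBParams()
    n = len(topology)
    all_idx = set(range(n))
    g1 = set(group1) if group1 is not None else all_idx
    g2 = set(group2) if group2 is not None else all_idx
    same_group_default = group1 is None and group2 is None

    donors = [
        i
        for i in range(n)
        if topology[i].atom_name.upper() in params.donors and (i in g1 or i in g2)
    ]
    acceptors = [
        i for i in range(n) if topology[i].atom_name.upper() in params.acceptors
    ]
    coords = frame.coords
    found: list[tuple[int, int, int]] = []
    for d in donors:
        hs = _attached_hydrogens(frame, topology, d)
        if not hs:
            logger.warning(
                "donor %s %s:%d has no attached hydrogen; skipped",
                topology[d].atom_name,
                topology[d].chain_id,
                topology[d].residue_index,
            )
            continue
        for a in acceptors:
            if a == d:
                continue
            if same_group_default:
                if (topology[d].chain_id, topology[d].residue_index) == (
                    topology[a].chain_id,
                    topology[a].residue_index,
                ):
                    continue
            elif not ((d in g1 and a in g2) or (d in g2 and a in g1)):
                continue
            r_da = np.linalg.norm(coords[d] - coords[a])
            if r_da > params.da_cutoff:
                continue
            for h in hs:
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= params.dha_min_angle:
                    found.append((d, h, a))
    return found


def backbone_hb_count(
    frame: Frame,
    topology: Sequence[AtomRecord],
    params: HBParams | None = None,
) -> int:
    """Number of inter-chain backbone-backbone hydrogen bonds.

    Counts distinct donor-acceptor pairs where both atoms are backbone
    atoms and the donor and acceptor sit on different chains.
    """
    bb = [i for i, a in enumerate(topology) if a.is_backbone or a.element == "H"]
    bonds = detect_hbonds(frame, topology, params, group1=bb, group2=bb)
    pairs = {
        (d, a)
        for d, _, a in bonds
        if topology[d].is_backbone
        and topology[a].is_backbone
        and topology[d].chain_id != topology[a].chain_id
    }
    return len(pairs)


def _residue_label(topology: Sequence[AtomRecord], key: ResidueKey) -> str:
    for a in topology:
        if (a.chain_id, a.residue_index) == key:
            return f"{a.chain_id}:{a.residue_name}{a.residue_index}"
    raise KeyError(key)


def _group_residues(
    traj: Trajectory, group1: str | None, group2: str | None
) -> tuple[list[ResidueKey], list[ResidueKey]]:
    keys = traj.residue_keys()
    if group1 is None or group2 is None:
        chains = traj.chain_ids()
        if len(chains) != 2:
            raise ValueError(
                "default contact-map groups need exactly two chains; "
                "pass chain ids explicitly"
            )
        group1, group2 = chains
    r1 = [k for k in keys if k[0] == group1]
    r2 = [k for k in keys if k[0] == group2]
    if not r1 or not r2:
        raise ValueError("empty residue group for contact map")
    return r1, r2


def contact_probability_map(
    traj: Trajectory,
    kind: str = "sidechain",
    params: HBParams | None = None,
    cutoff: float = 6.5,
    group1: str | None = None,
    group2: str | None = None,
    equilibration_cut: float = 0.0,
    whole_residue: bool = False,
) -> ContactMap:
    """Per-residue-pair contact (or H-bond) probability over retained frames.

    Frames with time >= ``equilibration_cut`` (ns) are retained.  Groups
    are chains; by default the trajectory's two chains.
    """
    if kind not in ("sidechain", "hbond"):
        raise ValueError("kind must be 'sidechain' or 'hbond'")
    frames = [f for f in traj.frames if f.time >= equilibration_cut]
    if not frames:
        raise ValueError("no frames after the equilibration cut")
    r1, r2 = _group_residues(traj, group1, group2)
    topo = traj.topology
    residues = _residue_atoms(topo)
    counts = np.zeros((len(r1), len(r2)))
    for frame in frames:
        if kind == "sidechain":
            com1 = [
                _sidechain_com(frame, topo, residues[k], whole_residue) for k in r1
            ]
            com2 = [
                _sidechain_com(frame, topo, residues[k], whole_residue) for k in r2
            ]
            d = np.linalg.norm(
                np.asarray(com1)[:, None, :] - np.asarray(com2)[None, :, :], axis=-1
            )
            counts += d <= cutoff
        else:
            bonds = detect_hbonds(frame, topo, params)
            index1 = {k: i for i, k in enumerate(r1)}
            index2 = {k: j for j, k in enumerate(r2)}
            hit = np.zeros_like(counts, dtype=bool)
            for d_, _, a_ in bonds:
                kd = (topo[d_].chain_id, topo[d_].residue_index)
                ka = (topo[a_].chain_id, topo[a_].residue_index)
                if kd in index1 and ka in index2:
                    hit[index1[kd], index2[ka]] = True
                if ka in index1 and kd in index2:
                    hit[index1[ka], index2[kd]] = True
            counts += hit
    values = counts / len(frames)
    return ContactMap(
        row_labels=[_residue_label(topo, k) for k in r1],
        col_labels=[_residue_label(topo, k) for k in r2],
        values=values,
        kind=kind,
    )


def residue_pair_energy(
    frame: Frame,
    topology: Sequence[AtomRecord],
    res_i: ResidueKey,
    res_j: ResidueKey,
) -> float:
    """Coulomb + Lennard-Jones interaction energy of two residues (kcal/mol).

    Sums 332.0636 q_i q_j / r + 4 eps_ij ((sig_ij/r)^12 - (sig_ij/r)^6)
    over inter-residue atom pairs, sigma combined arithmetically and
    epsilon geometrically (Lorentz-Berthelot).  Every atom of both
    residues must carry charge and LJ parameters.
    """
    residues = _residue_atoms(topology)
    for key in (res_i, res_j):
        if key not in residues:
            raise KeyError(f"residue {key} not in topology")
    idx_i, idx_j = residues[res_i], residues[res_j]
    for i in idx_i + idx_j:
        a = topology[i]
        if a.charge is None or a.lj_sigma is None or a.lj_epsilon is None:
            raise ValueError(
                f"atom {a.atom_name} {a.chain_id}:{a.residue_index} lacks "
                "charge/LJ parameters"
            )
    e = 0.0
    for i in idx_i:
        ai = topology[i]
        for j in idx_j:
            aj = topology[j]
            r = float(np.linalg.norm(frame.coords[i] - frame.coords[j]))
            if r == 0.0:
                raise ValueError("overlapping atoms in residue pair energy")
            e += COULOMB_KCAL_A_E2 * ai.charge * aj.charge / r
            eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            if eps > 0:
                sig = 0.5 * (ai.lj_sigma + aj.lj_sigma)
                sr6 = (sig / r) ** 6
                e += 4.0 * eps * (sr6 * sr6 - sr6)
    return e


def energy_map(
    traj: Trajectory,
    group1: str | None = None,
    group2: str | None = None,
    equilibration_cut: float = 0.0,
) -> ContactMap:
    """Frame-averaged residue-pair interaction-energy map (kcal/mol)."""
    frames = [f for f in traj.frames if f.time >= equilibration_cut]
    if not frames:
        raise ValueError("no frames after the equilibration cut")
    r1, r2 = _group_residues(traj, group1, group2)
    topo = traj.topology
    values = np.zeros((len(r1), len(r2)))
    for frame in frames:
        for a, ki in enumerate(r1):
            for b, kj in enumerate(r2):
                values[a, b] += residue_pair_energy(frame, topo, ki, kj)
    values /= len(frames)
    return ContactMap(
        row_labels=[_residue_label(topo, k) for k in r1],
        col_labels=[_residue_label(topo, k) for k in r2],
        values=values,
        kind="energy",
    )
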