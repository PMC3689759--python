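"""Kabsch superposition, Ca-RMSD series and RMSD-cutoff clustering.

Clustering follows the greedy gromos scheme: compute all pairwise
best-fit RMSDs, repeatedly take the frame with the most neighbors within
the cutoff as a cluster center, remove it and its neighbors, and repeat.
Each pair is superposed with its own optimal rotation; the fitted RMSD is
therefore symmetric and non-negative but not a metric (no triangle
inequality is relied on).  Ties in neighbor count are broken by the
lowest frame index so results are deterministic.

RMSD values are reported in nm, the unit conventional for protein-scale
trajectory analysis; coordinates themselves stay in A.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Frame, Trajectory, select_atoms

__all__ = [
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_series",
    "daura_cluster",
    "cluster_from_distance_matrix",
    "pairwise_rmsd_matrix",
]


@dataclass
class ClusterResult:
    """RMSD-cutoff clustering outcome.

    ``assignment[i]`` is the (0-based) cluster id of frame i, ids ordered
    by extraction so populations are non-increasing; ``centers[k]`` is the
    representative (center) frame of cluster k.
    """

    assignment: np.ndarray
    centers: list[int]
    populations: list[int]
    cutoff: float

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if sum(self.populations) != len(self.assignment):
            raise ValueError("populations must sum to the number of frames")
        for k, c in enumerate(self.centers):
            if self.assignment[c] != k:
                raise ValueError("each center must belong to its own cluster")


def kabsch_superpose(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of y onto x.

    Returns (R, t, rmsd) with x ~ R @ y + t, R a proper rotation
    (reflections excluded) and rmsd in the input length unit after the
    transform.  Requires >= 3 non-collinear points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("x and y must be matching (n, 3) arrays")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    xm = (w[:, None] * x).sum(axis=0)
    ym = (w[:, None] * y).sum(axis=0)
    xc = x - xm
    yc = y - ym
    # collinearity check on either set
    for c in (xc, yc):
        if np.linalg.matrix_rank(c, tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) point set")
    h = (yc * w[:, None]).T @ xc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = xm - rot @ ym
    diff = (rot @ yc.T).T - xc
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return rot, t, rmsd


def _frame_coords(frames: Sequence[Frame], idx: np.ndarray) -> list[np.ndarray]:
    return [f.coords[idx] for f in frames]


def rmsd_series(
    traj: Trajectory,
    reference: int | Frame = 0,
    selection: str = "name CA",
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Best-fit RMSD of every frame against a reference, in nm."""
    idx = np.asarray(select_atoms(traj, selection), dtype=int)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    ref = traj.frames[reference] if isinstance(reference, int) else reference
    ref_xyz = ref.coords[idx]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        _, _, rmsd_a = kabsch_superpose(ref_xyz, frame.coords[idx], weights)
        out[i] = rmsd_a / 10.0
    return out


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: str = "name CA"
) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs (nm)."""
    idx = np.asarray(select_atoms(traj, selection), dtype=int)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    xyz = _frame_coords(traj.frames, idx)
    n = len(xyz)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch_superpose(xyz[i], xyz[j])
            d[i, j] = d[j, i] = r / 10.0
    return d


def cluster_from_distance_matrix(dist: np.ndarray, cutoff: float) -> ClusterResult:
    """Greedy gromos clustering of a precomputed symmetric distance matrix."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    unassigned = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    centers: list[int] = []
    populations: list[int] = []
    while unassigned.any():
        neighbor = (dist <= cutoff) & unassigned[None, :]
        counts = np.where(unassigned, neighbor.sum(axis=1), -1)
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(neighbor[center] & unassigned)[0]
        k = len(centers)
        assignment[members] = k
        centers.append(center)
        populations.append(len(members))
        unassigned[members] = False
    return ClusterResult(
        assignment=assignment, centers=centers, populations=populations, cutoff=cutoff
    )


def daura_cluster(
    traj: Trajectory, selection: str = "name CA", cutoff: float = 0.2
) -> ClusterResult:
    """RMSD-cutoff (gromos) clustering of trajectory frames.

    ``cutoff`` is in nm (typical tolerances are 0.18-0.2 nm).
    """
    dist = pairwise_rmsd_matrix(traj, selection)
    return cluster_from_distance_matrix(dist, cutoff)
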