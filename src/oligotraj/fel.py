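"""Histogram-based free-energy landscapes over reaction coordinates.

The free energy over one or two reaction coordinates V is estimated from
the sampling histogram P(V) of a trajectory as

    dG(V) = -k_B T ln[ P(V) / P_max ],

so the modal bin is exactly 0 and every populated bin is >= 0.  k_B T is
expressed per mole via the gas constant (R = 1.987e-3 kcal/mol/K) so that
energies are in kcal/mol.  Empty bins are masked, never given a large
finite value.  No reweighting or kernel smoothing is applied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._constants import R_KCAL_PER_MOL_K

__all__ = ["FESGrid", "histogram", "free_energy_surface", "locate_minima"]


@dataclass
class FESGrid:
    """Binned free-energy surface (1-D or 2-D) with temperature metadata."""

    coord_names: tuple[str, ...]
    edges: list[np.ndarray]
    delta_g: np.ma.MaskedArray
    temperature: float
    n_samples: int

    def __post_init__(self):
        if len(self.edges) != self.delta_g.ndim:
            raise ValueError("edges/dimension mismatch")
        for ax, e in enumerate(self.edges):
            if len(e) - 1 != self.delta_g.shape[ax]:
                raise ValueError("bin count must be edges - 1 per axis")
        if self.delta_g.count() == 0:
            raise ValueError("all bins are empty")
        dg = self.delta_g.compressed()
        if dg.min() < -1e-9:
            raise ValueError("delta_g must be >= 0 with minimum 0")

    def bin_centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])


def histogram(
    streams: Sequence[np.ndarray] | np.ndarray,
    bins: int | Sequence[int] = 50,
    range: Sequence[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Normalized sampling histogram over 1 or 2 coordinate streams.

    Returns (P, edges) with P summing to 1.  Without an explicit range
    the observed span is padded by 1% per side so edge samples fall
    inside the grid.
    """
    arr = np.asarray(streams, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] not in (1, 2):
        raise ValueError("expected one or two coordinate streams")
    if arr.shape[1] == 0:
        raise ValueError("empty coordinate stream")
    if arr.shape[0] == 2 and arr.shape[1] < 1:
        raise ValueError("streams must have equal, non-zero length")
    ndim = arr.shape[0]
    if np.isscalar(bins):
        bins = [int(bins)] * ndim
    if any(b < 2 for b in bins):
        raise ValueError("need at least 2 bins per axis")
    if range is None:
        range = []
        for axis in np.arange(ndim):
            lo, hi = arr[axis].min(), arr[axis].max()
            pad = 0.01 * (hi - lo) if hi > lo else max(abs(lo), 1.0) * 1e-6
            range.append((lo - pad, hi + pad))
    counts, edges = np.histogramdd(arr.T, bins=bins, range=range)
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fall inside the histogram range")
    return counts / total, list(edges)


def free_energy_surface(
    p: np.ndarray,
    edges: Sequence[np.ndarray],
    temperature: float = 300.0,
    coord_names: Sequence[str] | None = None,
    n_samples: int | None = None,
) -> FESGrid:
    """dG = -RT ln(P / P_max); empty bins masked."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    p = np.asarray(p, dtype=float)
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("probability grid is all zero")
    rt = R_KCAL_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        dg = -rt * np.log(np.where(p > 0, p / pmax, np.nan))
    masked = np.ma.masked_invalid(dg)
    names = tuple(coord_names) if coord_names else tuple(f"coord{i}" for i in range(p.ndim))
    return FESGrid(
        coord_names=names,
        edges=[np.asarray(e) for e in edges],
        delta_g=masked,
        temperature=temperature,
        n_samples=int(n_samples) if n_samples is not None else -1,
    )


def locate_minima(fes: FESGrid, depth_cut: float = np.inf) -> list[tuple[tuple[float, ...], float]]:
    """Local minima (4-neighborhood; 2 in 1-D) with dG <= depth_cut.

    Masked neighbors count as infinitely high.  Returned as
    (bin-center coordinates, dG), sorted ascending by dG.
    """
    dg = fes.delta_g.filled(np.inf)
    minima = []
    it = np.ndindex(*dg.shape)
    for idx in it:
        val = dg[idx]
        if not np.isfinite(val) or val > depth_cut:
            continue
        is_min = True
        for axis in range(dg.ndim):
            for step in (-1, 1):
                nb = list(idx)
                nb[axis] += step
                if 0 <= nb[axis] < dg.shape[axis] and dg[tuple(nb)] < val:
                    is_min = False
                    break
            if not is_min:
                break
        if is_min:
            center = tuple(float(fes.bin_centers(ax)[i]) for ax, i in enumerate(idx))
            minima.append((center, float(val)))
    return sorted(minima, key=lambda m: m[1])
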