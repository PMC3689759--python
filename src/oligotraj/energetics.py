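"""MM-PBSA binding free-energy aggregation and inhibition-constant estimate.

The end-point estimate combines, per snapshot or per trajectory mean, the
molecular-mechanics electrostatic (dE_elec) and van der Waals (dE_vdw)
interaction energies with nonpolar (dG_sur) and polar Poisson-Boltzmann
(dG_PB) solvation terms and a normal-mode entropy term (T*dS, stored as
tabulated, typically negative):

    dG_bind = dE_elec + dE_vdw + dG_sur + dG_PB - T*dS

All terms are in kcal/mol.  The per-snapshot terms themselves come from an
external MM-PBSA engine and are consumed here as tables; this module only
aggregates them and derives the dissociation/inhibition constant

    K_I = exp(dG_bind / (R T)),   R = 1.987e-3 kcal/mol/K,

which equals the IC50 under the Cheng-Prusoff noncompetitive (or
K_m << [S]) assumption.

Cross-trajectory spreads are population standard deviations (divisor N),
the convention that reproduces spreads quoted over small sets of repeat
trajectories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._constants import R_KCAL_PER_MOL_K

__all__ = [
    "EnergyComponentsRecord",
    "BindingSummary",
    "combine_components",
    "trajectory_mean",
    "summarize_trajectories",
    "inhibition_constant",
    "read_component_table",
    "write_summary",
]

COMPONENT_FIELDS = ("e_elec", "e_vdw", "g_sur", "g_pb", "t_ds")


@dataclass(frozen=True)
class EnergyComponentsRecord:
    """The five MM-PBSA terms (kcal/mol) for one snapshot or one mean."""

    e_elec: float
    e_vdw: float
    g_sur: float
    g_pb: float
    t_ds: float
    label: str = ""

    def __post_init__(self):
        for name in COMPONENT_FIELDS:
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite component {name}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in COMPONENT_FIELDS])


@dataclass(frozen=True)
class BindingSummary:
    """Cross-trajectory binding summary.

    ``component_mean``/``component_sd`` are 5-vectors ordered as
    (e_elec, e_vdw, g_sur, g_pb, t_ds); spreads are population SDs.
    """

    per_trajectory_dg: tuple[float, ...]
    component_mean: tuple[float, ...]
    component_sd: tuple[float, ...]
    delta_g_bind: float
    delta_g_sd: float
    k_i: float
    ic50: float
    temperature: float
    assumption_flag: str = "Cheng-Prusoff: noncompetitive or Km << [S]"

    def __post_init__(self):
        if self.k_i <= 0:
            raise ValueError("K_I must be positive")
        if any(s < 0 for s in self.component_sd) or self.delta_g_sd < 0:
            raise ValueError("spreads must be non-negative")


def combine_components(rec: EnergyComponentsRecord) -> float:
    """dG_bind = e_elec + e_vdw + g_sur + g_pb - t_ds (kcal/mol)."""
    return rec.e_elec + rec.e_vdw + rec.g_sur + rec.g_pb - rec.t_ds


def trajectory_mean(stream: Sequence[EnergyComponentsRecord]) -> EnergyComponentsRecord:
    """Component-wise arithmetic mean over a snapshot stream."""
    if len(stream) == 0:
        raise ValueError("empty component stream")
    arr = np.stack([r.as_array() for r in stream])
    m = arr.mean(axis=0)
    return EnergyComponentsRecord(*m, label=f"mean of {len(stream)}")


def summarize_trajectories(
    records: Sequence[EnergyComponentsRecord], temperature: float = 300.0
) -> BindingSummary:
    """Average per-trajectory component means and attach K_I / IC50.

    Spreads are population standard deviations (divisor N) over the
    per-trajectory values, for both the components and dG_bind.
    """
    if len(records) == 0:
        raise ValueError("need at least one trajectory record")
    arr = np.stack([r.as_array() for r in records])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    dgs = np.array([combine_components(r) for r in records])
    dg = float(dgs.mean())
    dg_sd = float(dgs.std(ddof=0))
    ki = inhibition_constant(dg, temperature)
    return BindingSummary(
        per_trajectory_dg=tuple(float(x) for x in dgs),
        component_mean=tuple(float(x) for x in mean),
        component_sd=tuple(float(x) for x in sd),
        delta_g_bind=dg,
        delta_g_sd=dg_sd,
        k_i=ki,
        ic50=ki,
        temperature=temperature,
    )


def inhibition_constant(delta_g: float, temperature: float = 300.0) -> float:
    """K_I = exp(dG_bind / RT) in mol/L; equals IC50 under Cheng-Prusoff."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return math.exp(delta_g / (R_KCAL_PER_MOL_K * temperature))


def read_component_table(path: str | Path) -> list[EnergyComponentsRecord]:
    """Read a per-snapshot component table (TSV/CSV).

    Requires columns e_elec, e_vdw, g_sur, g_pb, t_ds; an optional
    ``label`` column is carried through.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep)
    missing = set(COMPONENT_FIELDS) - set(table.columns)
    if missing:
        raise ValueError(f"component table {path} missing columns: {sorted(missing)}")
    out = []
    for i, row in table.iterrows():
        out.append(
            EnergyComponentsRecord(
                *(float(row[f]) for f in COMPONENT_FIELDS),
                label=str(row["label"]) if "label" in table.columns else str(i),
            )
        )
    if not out:
        raise ValueError(f"component table {path} is empty")
    return out


def write_summary(summary: BindingSummary, path: str | Path) -> None:
    """Write a one-row TSV mirroring the component-table layout plus K_I/IC50."""
    cols = {f"{f}_mean": [m] for f, m in zip(COMPONENT_FIELDS, summary.component_mean)}
    cols.update({f"{f}_sd": [s] for f, s in zip(COMPONENT_FIELDS, summary.component_sd)})
    cols["delta_g_bind"] = [summary.delta_g_bind]
    cols["delta_g_sd"] = [summary.delta_g_sd]
    cols["k_i_molar"] = [summary.k_i]
    cols["ic50_molar"] = [summary.ic50]
    cols["temperature_K"] = [summary.temperature]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
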