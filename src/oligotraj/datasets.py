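"""Literature reference values bundled with the package.

``MMPBSA_COMPONENTS`` holds the published per-trajectory MM-PBSA component
means (kcal/mol) for the insulin-binding peptides LVEALYL (insulin fragment
B11-17) and RGFFYT (B22-27), four independent all-atom MD trajectories
each.  Columns follow :mod:`oligotraj.energetics`:
(dE_elec, dE_vdw, dG_sur, dG_PB, T*dS).

These rows serve as worked-example inputs for the aggregation layer: the
combination rule and the cross-trajectory statistics can be checked
directly against the published per-row and average binding free energies.
"""
from __future__ import annotations

from .energetics import EnergyComponentsRecord

__all__ = ["MMPBSA_COMPONENTS"]

MMPBSA_COMPONENTS: dict[str, list[EnergyComponentsRecord]] = {
    "LVEALYL": [
        EnergyComponentsRecord(-74.7, -48.4, -7.2, 75.2, -41.3, label="traj1"),
        EnergyComponentsRecord(-81.7, -56.2, -7.6, 94.8, -39.8, label="traj2"),
        EnergyComponentsRecord(-68.9, -67.2, -8.4, 79.9, -40.3, label="traj3"),
        EnergyComponentsRecord(-86.9, -46.8, -6.3, 93.4, -38.4, label="traj4"),
    ],
    "RGFFYT": [
        EnergyComponentsRecord(-172.7, -50.0, -6.5, 187.4, -34.7, label="traj1"),
        EnergyComponentsRecord(-143.3, -40.5, -5.2, 143.9, -34.5, label="traj2"),
        EnergyComponentsRecord(-95.1, -55.6, -6.3, 108.3, -34.8, label="traj3"),
        EnergyComponentsRecord(-195.0, -46.9, -5.5, 188.6, -35.8, label="traj4"),
    ],
}

#: Published dG_bind (kcal/mol) per trajectory, for cross-checks.
PUBLISHED_DG_BIND: dict[str, list[float]] = {
    "LVEALYL": [-13.7, -10.9, -24.3, -8.2],
    "RGFFYT": [-7.2, -10.5, -13.9, -22.9],
}
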