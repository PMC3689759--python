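"""Configuration-driven orchestration of the full analysis.

A pipeline config is one YAML document with per-stage parameter blocks.
Enabled stages run in dependency order (simulate -> order -> fel ->
contacts -> cluster -> mmpbsa -> ss); each writes its TSV output into the
output directory and contributes a section to a single JSON report.  All
parameters actually used, including defaults, are echoed into the report
and logged, so a run is reproducible from its report alone.

Example config::

    seed: 7
    outdir: out/
    simulate:
      sequence: LVEALYL
      n_frames: 80
      transition_frame: 40
      orientation: antiparallel
      noise_sigma: 0.1
    order:
      p2_threshold: 0.9
      min_backbone_hb: 2
    fel:
      bins: 30
      temperature: 300.0
    cluster:
      cutoff: 0.2
      selection: name CA
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import conformation, contacts, fel, order, synth
from .core import Trajectory, read_structure, write_structure
from .energetics import read_component_table, summarize_trajectories

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
STAGES = ("simulate", "order", "fel", "contacts", "cluster", "mmpbsa", "ss")


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    traj_path: Path | None = None
    dt: float = 1.0
    stages: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    outdir = doc.pop("outdir", "oligotraj_out")
    seed = int(doc.pop("seed", 0))
    traj_path = doc.pop("traj", None)
    dt = float(doc.pop("dt", 1.0))
    stages = {k: (v or {}) for k, v in doc.items()}
    return PipelineConfig(
        outdir=outdir,
        seed=seed,
        traj_path=Path(traj_path) if traj_path else None,
        dt=dt,
        stages=stages,
    )


def _with_defaults(params: dict[str, Any], defaults: dict[str, Any]) -> dict[str, Any]:
    used = dict(defaults)
    for key, value in params.items():
        if key not in defaults:
            raise ValueError(f"unknown stage parameter {key!r}")
        used[key] = value
    for key in defaults:
        if key not in params:
            logger.info("parameter %s defaulted to %r", key, defaults[key])
    return used


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute enabled stages; returns (and writes) the JSON report."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "stages": {},
    }
    traj: Trajectory | None = None
    series: order.OrderSeries | None = None

    try:
        if "simulate" in config.stages:
            params = _with_defaults(
                config.stages["simulate"],
                {
                    "sequence": "LVEALYL",
                    "n_frames": 100,
                    "dt": 0.1,
                    "transition_frame": 50,
                    "orientation": "antiparallel",
                    "noise_sigma": 0.1,
                },
            )
            scenario = synth.DimerScenario(seed=config.seed, **params)
            traj = synth.generate_dimer_trajectory(scenario)
            out = config.outdir / "trajectory.pdb"
            write_structure(traj, out)
            report["stages"]["simulate"] = {
                "params": {**params, "seed": config.seed},
                "trajectory": str(out),
                "n_frames": traj.n_frames,
                "n_atoms": traj.n_atoms,
            }
        elif config.traj_path is not None:
            traj = read_structure(config.traj_path, dt=config.dt)

        if "order" in config.stages:
            if traj is None:
                raise ValueError("order stage needs a trajectory (simulate or traj:)")
            params = _with_defaults(
                config.stages["order"],
                {"p2_threshold": 0.9, "min_backbone_hb": 2, "persistence": 1},
            )
            criterion = order.FibrilCriterion(**params)
            series = order.order_series(traj, criterion=criterion)
            tau = order.first_passage(series, criterion)
            out = config.outdir / "order.tsv"
            series.to_frame().to_csv(out, sep="\t", index=False)
            report["stages"]["order"] = {
                "params": params,
                "output": str(out),
                "fibril_time_ns": tau,
                "mean_p2": float(series.p2.mean()),
            }

        if "fel" in config.stages:
            if series is None:
                raise ValueError("fel stage needs the order stage")
            params = _with_defaults(
                config.stages["fel"], {"bins": 50, "temperature": 300.0, "depth_cut": 1.0}
            )
            p, edges = fel.histogram([series.p2, series.cos_theta], bins=params["bins"])
            grid = fel.free_energy_surface(
                p,
                edges,
                temperature=params["temperature"],
                coord_names=("p2", "cos_theta"),
                n_samples=len(series.p2),
            )
            minima = fel.locate_minima(grid, depth_cut=params["depth_cut"])
            out = config.outdir / "fes.tsv"
            np.savetxt(out, grid.delta_g.filled(np.nan), delimiter="\t")
            report["stages"]["fel"] = {
                "params": params,
                "output": str(out),
                "minima": [{"coords": list(c), "delta_g": g} for c, g in minima[:5]],
            }

        if "contacts" in config.stages:
            if traj is None:
                raise ValueError("contacts stage needs a trajectory")
            params = _with_defaults(
                config.stages["contacts"],
                {"kind": "sidechain", "cutoff": 6.5, "equilibration_cut": 0.0},
            )
            cmap = contacts.contact_probability_map(
                traj,
                kind=params["kind"],
                cutoff=params["cutoff"],
                equilibration_cut=params["equilibration_cut"],
            )
            out = config.outdir / f"contacts_{params['kind']}.tsv"
            cmap.to_frame().to_csv(out, sep="\t")
            flat = cmap.to_frame().stack().sort_values(ascending=False)
            report["stages"]["contacts"] = {
                "params": params,
                "output": str(out),
                "top_contacts": [
                    {"pair": list(map(str, k)), "value": float(v)}
                    for k, v in flat.head(5).items()
                ],
            }

        if "cluster" in config.stages:
            if traj is None:
                raise ValueError("cluster stage needs a trajectory")
            params = _with_defaults(
                config.stages["cluster"],
                {"cutoff": 0.2, "selection": "name CA", "skip_ns": 0.0},
            )
            frames = [f for f in traj.frames if f.time >= params["skip_ns"]]
            sub = Trajectory(topology=traj.topology, frames=frames)
            result = conformation.daura_cluster(
                sub, selection=params["selection"], cutoff=params["cutoff"]
            )
            out = config.outdir / "clusters.tsv"
            with open(out, "w") as fh:
                fh.write("frame\tcluster\n")
                for i, c in enumerate(result.assignment):
                    fh.write(f"{i}\t{c}\n")
            report["stages"]["cluster"] = {
                "params": params,
                "output": str(out),
                "n_clusters": len(result.centers),
                "populations": result.populations,
                "centers": result.centers,
            }

        if "mmpbsa" in config.stages:
            params = _with_defaults(
                config.stages["mmpbsa"], {"components": [], "temperature": 300.0}
            )
            if not params["components"]:
                raise ValueError("mmpbsa stage needs component table paths")
            from .energetics import trajectory_mean

            records = [
                trajectory_mean(read_component_table(p)) for p in params["components"]
            ]
            summary = summarize_trajectories(records, params["temperature"])
            out = config.outdir / "mmpbsa.tsv"
            from .energetics import write_summary

            write_summary(summary, out)
            report["stages"]["mmpbsa"] = {
                "params": params,
                "output": str(out),
                "delta_g_bind": summary.delta_g_bind,
                "delta_g_sd": summary.delta_g_sd,
                "k_i_molar": summary.k_i,
                "ic50_molar": summary.ic50,
            }

        if "ss" in config.stages:
            params = _with_defaults(
                config.stages["ss"], {"assign": None, "window": None}
            )
            if not params["assign"]:
                raise ValueError("ss stage needs an assignment table path")
            from .ss import class_content, parse_assignments

            assignment = parse_assignments(params["assign"])
            window = tuple(params["window"]) if params["window"] else None
            per_res, overall = class_content(assignment, window)
            out = config.outdir / "ss_content.tsv"
            per_res.to_csv(out, sep="\t")
            report["stages"]["ss"] = {
                "params": params,
                "output": str(out),
                "overall_percent": {k: float(v) for k, v in overall.items()},
            }
    except Exception as exc:
        # keep partial outputs; name the failing stage in the error
        done = list(report["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc

    report_path = config.outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", report_path)
    return report
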