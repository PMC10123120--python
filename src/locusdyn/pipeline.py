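"""End-to-end reproducible pipeline: simulate -> render -> localize -> track
-> analyze -> classify.

Each stage reads and writes plain CSV/TIFF/JSON in the run directory so any
stage can be re-run or validated in isolation; skipping an upstream stage
resumes from its on-disk output.  In trajectory-only mode (``render`` and
``localize`` excluded) the tracker consumes ground-truth positions,
optionally perturbed by Gaussian localization noise, instead of image-derived
detections.  The resolved configuration is written beside the outputs and
every threshold used is echoed into the summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from locusdyn import classify as _classify
from locusdyn import dynamics as _dynamics
from locusdyn import track as _track
from locusdyn.config import CONDITION_PRESETS, RunConfig
from locusdyn.localize import localize_stack
from locusdyn.synthetic.population import (
    GroundTruth,
    add_localization_noise,
    simulate_population,
)
from locusdyn.synthetic.render import render_stack, write_stacks
from locusdyn.trajectory import trajectories_from_frame, trajectories_to_frame

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "apply_condition", "analyze_trajectories", "classify_trajectories"]


def apply_condition(config: RunConfig) -> RunConfig:
    """Return a copy of ``config`` with its condition preset applied."""
    preset = CONDITION_PRESETS[config.condition]
    pop = dataclasses.replace(config.population)
    if "alpha_x" in preset:
        pop = dataclasses.replace(pop, attB_alpha_x=preset["alpha_x"])
    if "alpha_y" in preset:
        pop = dataclasses.replace(pop, attB_alpha_y=preset["alpha_y"])
    if "D_scale" in preset:
        pop = dataclasses.replace(
            pop,
            attB_D_x=pop.attB_D_x * preset["D_scale"],
            attB_D_y=pop.attB_D_y * preset["D_scale"],
        )
    if "class_fractions" in preset:
        pop = dataclasses.replace(pop, class_fractions=dict(preset["class_fractions"]))
    pop = dataclasses.replace(pop, seed=config.seed, dt=config.dt, pixel_size=config.pixel_size)
    return dataclasses.replace(config, population=pop)


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, which stage '{producer}' produces; "
            f"run '{producer}' first or place the file in the run directory"
        )
    return path


def _fit_to_dict(fit: _dynamics.PowerLawFit) -> dict:
    return {
        "D": fit.D,
        "alpha": fit.alpha,
        "D_se": fit.D_se,
        "alpha_se": fit.alpha_se,
        "lag_range": list(fit.lag_range),
        "n_points": fit.n_points,
    }


def analyze_trajectories(trajs, config: RunConfig) -> dict:
    """MSD fits per component, VACF collapse and ergodicity for attB loci."""
    attb = [t for t in trajs if t.channel == "red"]
    if len(attb) < 10:
        raise ValueError(f"analysis needs at least 10 attB trajectories, got {len(attb)}")
    out: dict = {"n_attb_trajectories": len(attb), "fit_lag_range": list(config.fit_lag_range)}
    for component in ("r2d", "x", "y"):
        report = _dynamics.ergodicity_report(attb, component, config.fit_lag_range)
        out[component] = {
            "ta": _fit_to_dict(report.ta_fit),
            "ea": _fit_to_dict(report.ea_fit),
            "ergodic": report.ergodic,
            "alpha_diff_z": report.z,
        }
    alpha_2d = out["r2d"]["ta"]["alpha"]
    wd = _dynamics.walk_fractal_dimension(alpha_2d)
    out["walk_dimension"] = {"d_w": wd.d_w, "compact": wd.compact}
    vacfs = [_dynamics.vacf(attb, delta=m) for m in config.vacf_deltas]
    collapse = _dynamics.rescale_collapse(vacfs, alpha=alpha_2d, xi_max=4.0)
    out["vacf"] = {
        "deltas_frames": list(config.vacf_deltas),
        "rms_spread": collapse.rms_spread,
        "rms_vs_fbm_theory": collapse.rms_theory,
        "min_xi": float(collapse.table["mean"].idxmin()),
    }
    out["_tables"] = {
        "vacf_collapse": collapse.table,
        "msd_ta": pd.DataFrame(
            {
                "lag_s": (m := _dynamics.ta_msd_ensemble(attb, "r2d")).lags_s,
                "msd_r2d": m.msd,
                "msd_x": _dynamics.ta_msd_ensemble(attb, "x").msd,
                "msd_y": _dynamics.ta_msd_ensemble(attb, "y").msd,
            }
        ),
    }
    return out


def classify_trajectories(trajs, cell_lengths: pd.Series, config: RunConfig) -> dict:
    """Behaviour labels, class fractions and position distributions."""
    ices = [t for t in trajs if t.channel == "green"]
    attbs = [t for t in trajs if t.channel == "red"]
    by_cell: dict[int, list] = {}
    for a in attbs:
        by_cell.setdefault(a.cell_id, []).append(a)
    distances = {}
    for ice in ices:
        if ice.cell_id in by_cell:
            distances[ice.cell_id] = _track.nearest_attb_distance(ice, by_cell[ice.cell_id])
    labels = _classify.classify_population(ices, distances, cell_lengths)
    fractions = _classify.class_fractions(labels)
    mobile = _classify.mobility_filter(ices, _classify.ClassifierThresholds().mobility_step_nm)
    attb_dist = _classify.position_distribution(attbs, cell_lengths, tag="attB")
    ice_dist = _classify.position_distribution(mobile, cell_lengths, tag="mobile element")
    frac = {row["label"]: row for _, row in fractions.iterrows()}
    mobile_frac = sum(frac[l]["fraction"] for l in ("mobile_fast", "mobile_local") if l in frac)
    return {
        "n_cells": len(ices),
        "thresholds": dataclasses.asdict(_classify.ClassifierThresholds()),
        "fractions": {
            r["label"]: {"fraction": r["fraction"], "se": r["se"], "count": int(r["count"])}
            for _, r in fractions.iterrows()
        },
        "mobile_not_integrated_fraction": float(mobile_frac),
        "attb_position_peaks": [float(p) for p in attb_dist.peaks[:2]],
        "mobile_ice_position_peaks": [float(p) for p in ice_dist.peaks[:1]],
        "_tables": {
            "labels": labels,
            "fractions": fractions,
            "attb_positions": pd.DataFrame(
                {"bin_left": attb_dist.edges[:-1], "count": attb_dist.counts}
            ),
            "ice_positions": pd.DataFrame(
                {"bin_left": ice_dist.edges[:-1], "count": ice_dist.counts}
            ),
        },
    }


def _pop_tables(d: dict, out_dir: Path, prefix: str) -> dict:
    for name, table in d.pop("_tables", {}).items():
        table.to_csv(out_dir / f"{prefix}{name}.csv", index=True)
    return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    config = apply_condition(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(handler)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed, "condition": config.condition, "stages": list(config.stages)}
    truth: GroundTruth | None = None
    imaging = "render" in config.stages and "localize" in config.stages

    try:
        if "simulate" in config.stages:
            log.info("simulate: %d cells, seed %d", config.population.n_cells, config.seed)
            truth = simulate_population(config.population)
            truth.to_frame().to_csv(out / "truth.csv", index=False)
            truth.cell_lengths().rename_axis("cell_id").reset_index().to_csv(
                out / "cells.csv", index=False
            )

        if "render" in config.stages:
            if truth is None:
                raise FileNotFoundError(
                    "stage 'render' needs the in-memory population from stage 'simulate'"
                )
            for field_id in range(truth.n_fields):
                result = render_stack(truth, field_id)
                write_stacks(result, truth, out / "stacks")
            summary["n_fields"] = truth.n_fields

        if "localize" in config.stages:
            import tifffile

            stack_dir = _require(out / "stacks", "localize", "render")
            frames = []
            for phase_path in sorted(stack_dir.glob("field*_phase.tif")):
                tag = phase_path.name.split("_")[0]
                stacks = {
                    ch: tifffile.imread(stack_dir / f"{tag}_{ch}.tif")
                    for ch in ("phase", "green", "red")
                }
                det = localize_stack(
                    stacks, config.pixel_size, config.threshold_k, dt=config.dt
                )
                det["field"] = tag
                frames.append(det)
            detections = pd.concat(frames, ignore_index=True)
            detections.to_csv(out / "detections.csv", index=False)

        if "track" in config.stages:
            if imaging:
                det = pd.read_csv(_require(out / "detections.csv", "track", "localize"))
            else:
                # trajectory-only mode: ground truth plus localization noise
                truth_df = pd.read_csv(_require(out / "truth.csv", "track", "simulate"))
                trajs = trajectories_from_frame(truth_df, dt=config.dt)
                if config.localization_noise > 0:
                    trajs = add_localization_noise(
                        trajs, config.localization_noise, config.seed
                    )
                det = trajectories_to_frame(trajs)
            linked = _track.link(
                det, config.max_disp, config.max_gap, config.min_len, dt=config.dt
            )
            trajectories_to_frame(linked).to_csv(out / "trajectories.csv", index=False)
            ices = [t for t in linked if t.channel == "green"]
            attbs: dict[int, list] = {}
            for a in linked:
                if a.channel == "red":
                    attbs.setdefault(a.cell_id, []).append(a)
            series = [
                _track.nearest_attb_distance(i, attbs[i.cell_id])
                for i in ices
                if i.cell_id in attbs
            ]
            _track.distances_frame(series).to_csv(out / "distances.csv", index=False)
            summary["n_trajectories"] = len(linked)

        if "analyze" in config.stages:
            df = pd.read_csv(_require(out / "trajectories.csv", "analyze", "track"))
            trajs = trajectories_from_frame(df, dt=config.dt)
            summary["dynamics"] = _pop_tables(
                analyze_trajectories(trajs, config), out, "analysis_"
            )

        if "classify" in config.stages:
            df = pd.read_csv(_require(out / "trajectories.csv", "classify", "track"))
            trajs = trajectories_from_frame(df, dt=config.dt)
            lengths_df = pd.read_csv(_require(out / "cells.csv", "classify", "simulate"))
            lengths = lengths_df.set_index("cell_id")["length_nm"]
            summary["classification"] = _pop_tables(
                classify_trajectories(trajs, lengths, config), out, "classify_"
            )

        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()
    return out
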