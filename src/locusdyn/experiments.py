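"""Reusable in-silico experiments: estimator and classifier recovery runs.

Each function simulates data at stated conditions with the package's own
generators, runs the corresponding measurement pipeline and returns the
recovered quantities.  The analysis drivers, the test suite and the
acceptance script all call these so the numbers they report are produced by
one code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from locusdyn import track as _track
from locusdyn.classify import class_fractions, classify_population
from locusdyn.config import FRAME_INTERVAL_S, PopulationConfig, SimConfig
from locusdyn.dynamics import (
    ergodicity_report,
    fit_power_law,
    rescale_collapse,
    ta_msd_ensemble,
    vacf,
)
from locusdyn.localize import localize_stack
from locusdyn.synthetic.models import simulate_ensemble
from locusdyn.synthetic.population import (
    add_localization_noise,
    simulate_population,
    tethered_pair_cell,
)
from locusdyn.synthetic.render import render_stack

__all__ = [
    "recover_msd_exponents",
    "classify_synthetic_population",
    "measure_pair_separation",
    "vacf_collapse_run",
    "ergodicity_run",
    "localization_benchmark",
]


def _subseeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def recover_msd_exponents(
    alpha_x: float,
    alpha_y: float,
    D_x: float = 1050.0,
    D_y: float = 1350.0,
    n_traj: int = 59,
    n_frames: int = 90,
    dt: float = FRAME_INTERVAL_S,
    n_seeds: int = 20,
    seed: int = 0,
    fit_lags: tuple[int, int] = (1, 10),
) -> dict:
    """Fit TA-MSD power laws on simulated FBM ensembles, per component.

    Returns seed-averaged fitted exponents for the 2D, longitudinal (y) and
    transversal (x) MSD.
    """
    out = {"r2d": [], "x": [], "y": []}
    for s in _subseeds(seed, n_seeds):
        cfg = SimConfig(
            alpha_x=alpha_x, alpha_y=alpha_y, D_x=D_x, D_y=D_y,
            dt=dt, n_frames=n_frames, n_traj=n_traj, seed=int(s),
        )
        trajs = simulate_ensemble(cfg)
        for comp in out:
            out[comp].append(fit_power_law(ta_msd_ensemble(trajs, comp), fit_lags).alpha)
    return {
        comp: {"alpha": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "n_seeds": n_seeds}
        for comp, v in out.items()
    }


def classify_synthetic_population(
    n_cells: int,
    seed: int = 0,
    class_fractions_in: dict[str, float] | None = None,
    localization_noise: float = 20.0,
) -> dict:
    """Generate, perturb and classify a population; return recovered fractions."""
    kwargs = {} if class_fractions_in is None else {"class_fractions": class_fractions_in}
    cfg = PopulationConfig(n_cells=n_cells, seed=seed, **kwargs)
    truth = simulate_population(cfg)
    trajs = truth.trajectories()
    if localization_noise > 0:
        trajs = add_localization_noise(trajs, localization_noise, seed=seed + 1)
    ices = [t for t in trajs if t.channel == "green"]
    by_cell: dict[int, list] = {}
    for t in trajs:
        if t.channel == "red":
            by_cell.setdefault(t.cell_id, []).append(t)
    dists = {i.cell_id: _track.nearest_attb_distance(i, by_cell[i.cell_id]) for i in ices}
    labels = classify_population(ices, dists, truth.cell_lengths())
    frac = class_fractions(labels).set_index("label")["fraction"].to_dict()
    for name in ("integrated", "mobile_fast", "mobile_local", "trapped"):
        frac.setdefault(name, 0.0)
    frac["mobile_not_integrated"] = frac["mobile_fast"] + frac["mobile_local"]
    return {"fractions": frac, "n": n_cells, "labels": labels, "truth": truth}


def measure_pair_separation(
    n_frames: int = 100,
    seed: int = 0,
    tether_distance: float = 200.0,
    psf_sigma: float = 130.0,
) -> dict:
    """Render a two-channel tethered pair and measure the fitted separation.

    One cell, one red and one green spot at the configured tether distance
    with per-frame random orientation; each channel is localized by
    Gaussian-plus-constant fitting and the per-frame Euclidean distance
    between the two fitted centers (cell frame) is averaged.
    """
    cfg = PopulationConfig(
        n_cells=1, n_frames=n_frames, seed=seed,
        tether_distance=tether_distance, psf_sigma=psf_sigma,
    )
    truth = tethered_pair_cell(cfg)
    stacks = render_stack(truth, 0).stacks
    det = localize_stack(stacks, cfg.pixel_size, dt=cfg.dt, refit_geometry=False)
    dists = []
    for _, g in det.groupby("frame"):
        green = g[g.channel == "green"]
        red = g[g.channel == "red"]
        if len(green) == 1 and len(red) == 1:
            dists.append(
                float(
                    np.hypot(
                        green.x_nm.iloc[0] - red.x_nm.iloc[0],
                        green.y_nm.iloc[0] - red.y_nm.iloc[0],
                    )
                )
            )
    dists = np.asarray(dists)
    return {
        "mean_nm": float(dists.mean()),
        "sd_nm": float(dists.std(ddof=1)),
        "n_frames": len(dists),
    }


def vacf_collapse_run(
    alpha: float = 0.36,
    D: float = 600.0,
    n_traj: int = 200,
    n_frames: int = 160,
    deltas: tuple[int, ...] = (1, 2, 4, 8),
    seed: int = 0,
    dt: float = FRAME_INTERVAL_S,
) -> dict:
    """FBM ensemble -> normalized VACF at several velocity intervals -> collapse."""
    cfg = SimConfig(
        alpha_x=alpha, alpha_y=alpha, D_x=D, D_y=D,
        dt=dt, n_frames=n_frames, n_traj=n_traj, seed=seed,
    )
    trajs = simulate_ensemble(cfg)
    results = [vacf(trajs, m) for m in deltas]
    collapse = rescale_collapse(results, alpha=alpha, xi_max=4.0)
    v1 = results[0]
    return {
        "rms_spread": collapse.rms_spread,
        "rms_vs_theory": collapse.rms_theory,
        "dip_at_xi1": float(v1.C_norm[1]),
        "dip_se": float(v1.C_norm_se[1]),
        "table": collapse.table,
    }


def ergodicity_run(
    model: str,
    seed: int = 0,
    n_traj: int = 400,
    n_frames: int = 150,
    dt: float = FRAME_INTERVAL_S,
) -> dict:
    """EA-vs-TA MSD consistency for one mechanism (fbm or ctrw)."""
    kw = dict(D_x=1000.0, D_y=1000.0, dt=dt, n_frames=n_frames, n_traj=n_traj, seed=seed)
    cfg = (
        SimConfig(model="fbm", alpha_x=0.5, alpha_y=0.5, **kw)
        if model == "fbm"
        else SimConfig(model="ctrw", ctrw_beta=0.5, **kw)
    )
    report = ergodicity_report(simulate_ensemble(cfg))
    return {
        "ergodic": report.ergodic,
        "z": report.z,
        "alpha_ta": report.ta_fit.alpha,
        "alpha_ea": report.ea_fit.alpha,
    }


def localization_benchmark(
    n_noiseless: int = 200,
    n_noisy: int = 300,
    seed: int = 0,
    psf_sigma_px: float = 130.0 / 109.76,
    photon_budget: float = 1500.0,
    background: float = 100.0,
    read_noise: float = 2.0,
) -> dict:
    """Bias and RMSE of the Gaussian fit on isolated rendered spots (nm)."""
    from locusdyn.config import PIXEL_SIZE_NM
    from locusdyn.localize import fit_spot_gaussian
    from locusdyn.synthetic.render import _add_spot

    rng = np.random.default_rng(seed)
    results = {}
    for tag, n, noisy in (("noiseless", n_noiseless, False), ("default_noise", n_noisy, True)):
        errs = []
        for _ in range(n):
            img = np.zeros((15, 15))
            col = 7 + rng.uniform(-0.5, 0.5)
            row = 7 + rng.uniform(-0.5, 0.5)
            _add_spot(img, col, row, psf_sigma_px, photon_budget if noisy else 1e5)
            if noisy:
                img = rng.poisson(img + background).astype(float)
                img += rng.standard_normal(img.shape) * read_noise
                img = np.rint(img)
            fit = fit_spot_gaussian(img, (7, 7))
            if fit is not None:
                errs.append((fit.col - col, fit.row - row))
        errs = np.array(errs) * PIXEL_SIZE_NM
        results[tag] = {
            "bias_nm": float(np.linalg.norm(errs.mean(axis=0))),
            "rmse_nm": float(np.sqrt(np.mean(np.sum(errs**2, axis=1) / 2))),
            "n": len(errs),
        }
    return results
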