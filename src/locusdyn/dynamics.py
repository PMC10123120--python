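"""Anomalous-diffusion statistics for locus trajectories.

Implements the quantities used to characterize subdiffusive locus motion
and to discriminate between candidate mechanisms:

* time-averaged and ensemble-averaged MSD, in 2D or per axis, with
  power-law fits ``MSD(tau) = D * tau**alpha`` by ordinary least squares in
  log-log coordinates;
* the velocity autocorrelation function
  ``C_u(tau) = <u(t + tau) . u(t)>`` with finite-difference velocities
  ``u(t) = (r(t + delta) - r(t)) / delta``, its normalization by ``C_u(0)``
  and its collapse under the rescaled lag ``xi = tau / delta``;
* the FBM closed form
  ``C(xi) = ((xi + 1)**alpha + |xi - 1|**alpha - 2 xi**alpha) / 2``,
  whose negative minimum at ``xi = 1`` signals antipersistent viscoelastic
  motion (absent for CTRW and obstructed diffusion);
* the ensemble-vs-time-average ergodicity comparison (CTRW breaks it,
  FBM does not);
* the walk fractal dimension ``d_w = 2 / alpha`` (compact, space-filling
  exploration when d_w exceeds the embedding dimension 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from locusdyn.trajectory import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "MSDResult",
    "PowerLawFit",
    "VACFResult",
    "CollapseResult",
    "ErgodicityReport",
    "WalkDimension",
    "ta_msd",
    "ta_msd_ensemble",
    "ea_msd",
    "fit_power_law",
    "vacf",
    "fbm_vacf_theory",
    "rescale_collapse",
    "ergodicity_report",
    "walk_fractal_dimension",
]

COMPONENTS = ("r2d", "x", "y")
#: default power-law fit range in lag indices (inclusive); lag 1 is excluded
#: by default to stay above the localization-noise floor of imaged data
DEFAULT_FIT_LAGS = (2, 10)
#: two-sided z threshold of the ergodicity verdict
ERGODICITY_Z = 1.96


def _component_displacement_sq(dxy: np.ndarray, component: str) -> np.ndarray:
    if component == "r2d":
        return np.sum(dxy**2, axis=-1)
    if component == "x":
        return dxy[..., 0] ** 2
    if component == "y":
        return dxy[..., 1] ** 2
    raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")


@dataclass
class MSDResult:
    """Lag-indexed mean square displacement, nm^2."""

    component: str
    lags_s: np.ndarray
    msd: np.ndarray  # ensemble mean over trajectories
    mode: str  # "time" or "ensemble"
    n_traj: int
    curves: np.ndarray | None = None  # (n_traj, n_lags), NaN where undefined
    counts: np.ndarray | None = None  # valid pairs (or trajectories) per lag


@dataclass
class PowerLawFit:
    """OLS fit of log MSD on log lag: MSD = D * tau**alpha."""

    D: float  # nm^2 / s^alpha
    alpha: float
    D_se: float
    alpha_se: float
    lag_range: tuple[int, int]
    n_points: int


@dataclass
class VACFResult:
    """Velocity autocorrelation at velocity interval delta."""

    delta_s: float
    dt: float
    lags_s: np.ndarray
    C: np.ndarray  # ensemble mean, nm^2/s^2
    C_norm: np.ndarray  # ensemble mean of per-trajectory C/C(0)
    C_norm_se: np.ndarray
    n_traj: int

    @property
    def xi(self) -> np.ndarray:
        return self.lags_s / self.delta_s


@dataclass
class CollapseResult:
    """Goodness of the xi = tau/delta collapse across velocity intervals."""

    table: pd.DataFrame  # one column per delta on a common xi grid
    rms_spread: float  # RMS across-delta spread (normalized units)
    rms_theory: float | None  # RMS deviation of the mean curve from FBM theory


@dataclass
class ErgodicityReport:
    """Time-averaged vs ensemble-averaged MSD power-law comparison."""

    component: str
    ta_fit: PowerLawFit
    ea_fit: PowerLawFit
    alpha_diff: float
    alpha_diff_se: float
    z: float
    ergodic: bool


@dataclass
class WalkDimension:
    d_w: float
    compact: bool  # d_w > 2: space-filling exploration


# --------------------------------------------------------------------------
# MSD


def _ta_msd_curve(traj: Trajectory, component: str, max_lag: int | None) -> tuple[np.ndarray, np.ndarray]:
    grid = traj.on_regular_grid()
    n = len(grid)
    kmax = max(1, n // 4) if max_lag is None else min(max_lag, n - 1)
    msd = np.full(kmax, np.nan)
    counts = np.zeros(kmax, int)
    for k in range(1, kmax + 1):
        d2 = _component_displacement_sq(grid[k:] - grid[:-k], component)
        valid = ~np.isnan(d2)
        counts[k - 1] = valid.sum()
        if counts[k - 1]:
            msd[k - 1] = np.mean(d2[valid])
    return msd, counts


def ta_msd(
    traj: Trajectory, component: str = "r2d", max_lag: int | None = None
) -> MSDResult:
    """Time-averaged MSD of one trajectory with overlapping windows.

    For lag ``k*dt`` the squared displacement is averaged over all valid
    start times; frames lost to gaps are excluded pairwise.  Lags are
    limited to a quarter of the trajectory span unless ``max_lag`` is given.
    """
    msd, counts = _ta_msd_curve(traj, component, max_lag)
    keep = counts > 0
    if not keep.all():
        log.warning("%d all-gap lags omitted", int((~keep).sum()))
    lags = (np.arange(1, len(msd) + 1) * traj.dt)[keep]
    return MSDResult(
        component=component,
        lags_s=lags,
        msd=msd[keep],
        mode="time",
        n_traj=1,
        counts=counts[keep],
    )


def ta_msd_ensemble(
    trajs: list[Trajectory], component: str = "r2d", max_lag: int | None = None
) -> MSDResult:
    """Mean over trajectories of the time-averaged MSD curves."""
    if not trajs:
        raise ValueError("no trajectories")
    dt = trajs[0].dt
    curves = [_ta_msd_curve(t, component, max_lag)[0] for t in trajs]
    n_lags = max(len(c) for c in curves)
    mat = np.full((len(curves), n_lags), np.nan)
    for i, c in enumerate(curves):
        mat[i, : len(c)] = c
    counts = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return MSDResult(
        component=component,
        lags_s=np.arange(1, n_lags + 1) * dt,
        msd=mean,
        mode="time",
        n_traj=len(trajs),
        curves=mat,
        counts=counts,
    )


def ea_msd(trajs: list[Trajectory], component: str = "r2d") -> MSDResult:
    """Ensemble-averaged MSD: squared displacement from each trajectory's
    first observed position, averaged across trajectories at fixed lag.
    """
    if len(trajs) < 10:
        raise ValueError("ensemble averaging requires at least 10 trajectories")
    dts = {round(t.dt, 9) for t in trajs}
    if len(dts) != 1:
        raise ValueError(f"trajectories have unequal frame intervals: {sorted(dts)}")
    dt = trajs[0].dt
    n_lags = max(t.frames[-1] - t.frames[0] for t in trajs)
    mat = np.full((len(trajs), n_lags), np.nan)
    for i, t in enumerate(trajs):
        grid = t.on_regular_grid()
        d2 = _component_displacement_sq(grid[1:] - grid[0], component)
        mat[i, : len(d2)] = d2
    counts = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    return MSDResult(
        component=component,
        lags_s=np.arange(1, n_lags + 1) * dt,
        msd=mean,
        mode="ensemble",
        n_traj=len(trajs),
        curves=mat,
        counts=counts,
    )


def fit_power_law(
    msd: MSDResult,
    lag_range: tuple[int, int] = DEFAULT_FIT_LAGS,
    weighted: bool = False,
) -> PowerLawFit:
    """Fit ``MSD = D * tau**alpha`` by (optionally weighted) log-log OLS.

    ``lag_range`` selects lag indices (inclusive); nonpositive MSD values in
    range are dropped with a warning.  ``weighted=True`` down-weights longer
    lags by the number of displacement pairs that entered each average.
    """
    base = float(np.min(np.diff(msd.lags_s))) if len(msd.lags_s) > 1 else float(msd.lags_s[0])
    k = np.rint(msd.lags_s / base).astype(int)
    lo, hi = lag_range
    sel = (k >= lo) & (k <= hi) & np.isfinite(msd.msd)
    pos = msd.msd > 0
    if np.any(sel & ~pos):
        log.warning("%d nonpositive MSD values dropped from fit", int(np.sum(sel & ~pos)))
    sel &= pos
    if sel.sum() < 4:
        raise ValueError(f"fewer than 4 usable lags in fit range {lag_range}")
    x = np.log(msd.lags_s[sel])
    z = np.log(msd.msd[sel])
    if weighted and msd.counts is not None:
        w = msd.counts[sel].astype(float)
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
        resid = z - X @ beta
        dof = max(sel.sum() - 2, 1)
        s2 = float(resid @ W @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ W @ X)
        intercept, slope = beta
        slope_se = float(np.sqrt(cov[1, 1]))
        intercept_se = float(np.sqrt(cov[0, 0]))
    else:
        res = stats.linregress(x, z)
        intercept, slope = res.intercept, res.slope
        slope_se, intercept_se = res.stderr, res.intercept_stderr
    D = float(np.exp(intercept))
    return PowerLawFit(
        D=D,
        alpha=float(slope),
        D_se=float(D * intercept_se),
        alpha_se=float(slope_se),
        lag_range=lag_range,
        n_points=int(sel.sum()),
    )


# --------------------------------------------------------------------------
# velocity autocorrelation


def fbm_vacf_theory(xi, alpha: float) -> np.ndarray:
    """Normalized FBM velocity autocorrelation at rescaled lag xi = tau/delta."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    xi = np.asarray(xi, float)
    if np.any(xi < 0):
        raise ValueError("xi must be non-negative")
    return ((xi + 1.0) ** alpha + np.abs(xi - 1.0) ** alpha - 2.0 * xi**alpha) / 2.0


def vacf(
    trajs: list[Trajectory],
    delta: int = 1,
    max_lag: int | None = None,
    min_pairs: int = 10,
) -> VACFResult:
    """Velocity autocorrelation at velocity interval ``delta`` frames.

    Per trajectory, finite-difference velocities over ``delta`` frames are
    correlated at lags ``tau = j*dt`` by time averaging; each trajectory
    contributes its normalized time-averaged curve with equal weight to the
    ensemble mean.
    """
    if delta < 1:
        raise ValueError("delta must be a positive multiple of the frame interval")
    if not trajs:
        raise ValueError("no trajectories")
    dt = trajs[0].dt
    span = min(len(t) for t in trajs) - 1
    if delta > span / 4:
        raise ValueError(f"delta={delta} frames exceeds a quarter of the span ({span})")
    if max_lag is None:
        max_lag = max(span - delta - min_pairs, 1)
    raw, norm = [], []
    for t in trajs:
        grid = t.on_regular_grid()
        u = (grid[delta:] - grid[:-delta]) / (delta * dt)
        jmax = min(max_lag, len(u) - min_pairs)
        if jmax < 0:
            continue
        c = np.full(max_lag + 1, np.nan)
        for j in range(jmax + 1):
            dots = np.sum(u[j:] * u[: len(u) - j], axis=1)
            valid = ~np.isnan(dots)
            if valid.sum() >= min_pairs:
                c[j] = np.mean(dots[valid])
        raw.append(c)
        norm.append(c / c[0] if c[0] else c)
    raw = np.array(raw)
    norm = np.array(norm)
    with np.errstate(invalid="ignore"):
        c_mean = np.nanmean(raw, axis=0)
        n_mean = np.nanmean(norm, axis=0)
        n_count = np.sum(~np.isnan(norm), axis=0)
        n_se = np.nanstd(norm, axis=0, ddof=1) / np.sqrt(np.maximum(n_count, 1))
    return VACFResult(
        delta_s=delta * dt,
        dt=dt,
        lags_s=np.arange(max_lag + 1) * dt,
        C=c_mean,
        C_norm=n_mean,
        C_norm_se=n_se,
        n_traj=len(raw),
    )


def rescale_collapse(
    results: list[VACFResult],
    alpha: float | None = None,
    xi_step: float = 0.25,
    xi_max: float | None = None,
) -> CollapseResult:
    """Re-index VACF curves on xi = tau/delta and quantify their collapse.

    The collapse statistic is the RMS, over a common xi grid, of the
    across-delta standard deviation of the normalized curves; when ``alpha``
    is given the RMS deviation of the collapsed mean from the FBM closed
    form is reported as well.
    """
    if len(results) < 2:
        raise ValueError("collapse needs at least 2 distinct velocity intervals")
    if len({r.delta_s for r in results}) != len(results):
        raise ValueError("velocity intervals must be distinct")
    common_max = min(np.nanmax(np.where(np.isnan(r.C_norm), -np.inf, r.xi)) for r in results)
    if xi_max is not None:
        common_max = min(common_max, xi_max)
    if common_max <= 0:
        raise ValueError("xi ranges do not overlap")
    grid = np.arange(0.0, common_max + 1e-9, xi_step)
    cols = {}
    for r in results:
        good = np.isfinite(r.C_norm)
        cols[f"delta={r.delta_s:g}s"] = np.interp(grid, r.xi[good], r.C_norm[good])
    table = pd.DataFrame(cols, index=pd.Index(grid, name="xi"))
    spread = table.std(axis=1, ddof=0).to_numpy()
    rms_spread = float(np.sqrt(np.mean(spread**2)))
    table["mean"] = table.mean(axis=1)
    rms_theory = None
    if alpha is not None:
        theory = fbm_vacf_theory(grid, alpha)
        table["fbm_theory"] = theory
        rms_theory = float(np.sqrt(np.mean((table["mean"].to_numpy() - theory) ** 2)))
    return CollapseResult(table=table, rms_spread=rms_spread, rms_theory=rms_theory)


# --------------------------------------------------------------------------
# ergodicity and walk dimension


def _refit_mean(result: MSDResult, pick: np.ndarray, lag_range) -> float:
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(result.curves[pick], axis=0)
    boot = MSDResult(result.component, result.lags_s, mean, result.mode, len(pick))
    return fit_power_law(boot, lag_range).alpha


def _bootstrap_alpha_diff_se(
    ta: MSDResult, ea: MSDResult, lag_range: tuple[int, int], n_boot: int, seed: int = 0
) -> float:
    """SE of (alpha_TA - alpha_EA) by resampling trajectories with replacement.

    OLS standard errors understate the uncertainty because MSD points share
    trajectories across lags; resampling the same trajectories into both
    averages also keeps the TA/EA correlation, sharpening the difference.
    """
    rng = np.random.default_rng(seed)
    n = ta.curves.shape[0]
    diffs = []
    for _ in range(n_boot):
        pick = rng.integers(0, n, size=n)
        try:
            diffs.append(
                _refit_mean(ta, pick, lag_range) - _refit_mean(ea, pick, lag_range)
            )
        except ValueError:
            continue
    return float(np.std(diffs, ddof=1))


def ergodicity_report(
    trajs: list[Trajectory],
    component: str = "r2d",
    lag_range: tuple[int, int] = DEFAULT_FIT_LAGS,
    n_boot: int = 200,
) -> ErgodicityReport:
    """Compare time-averaged and ensemble-averaged MSD power-law exponents.

    The process is called consistent with ergodicity when the exponents
    agree within a joint 95% interval whose standard errors come from a
    trajectory bootstrap; a significant mismatch is the ageing signature
    that excludes a CTRW mechanism.
    """
    ta = ta_msd_ensemble(trajs, component)
    ea = ea_msd(trajs, component)
    ta_fit = fit_power_law(ta, lag_range)
    ea_fit = fit_power_law(ea, lag_range)
    diff = ta_fit.alpha - ea_fit.alpha
    se = _bootstrap_alpha_diff_se(ta, ea, lag_range, n_boot)
    z = diff / se if se > 0 else np.inf
    return ErgodicityReport(
        component=component,
        ta_fit=ta_fit,
        ea_fit=ea_fit,
        alpha_diff=float(diff),
        alpha_diff_se=se,
        z=float(z),
        ergodic=bool(abs(z) < ERGODICITY_Z),
    )


def walk_fractal_dimension(alpha: float) -> WalkDimension:
    """Walk dimension d_w = 2/alpha of a trajectory with MSD exponent alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d_w = 2.0 / alpha
    return WalkDimension(d_w=float(d_w), compact=bool(d_w > 2.0))
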