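"""MSD, power-law fitting, velocity autocorrelation and ergodicity statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from locusdyn.config import SimConfig
from locusdyn.dynamics import (
    MSDResult,
    ea_msd,
    ergodicity_report,
    fbm_vacf_theory,
    fit_power_law,
    rescale_collapse,
    ta_msd,
    ta_msd_ensemble,
    vacf,
    walk_fractal_dimension,
)
from locusdyn.synthetic.models import simulate_ensemble
from locusdyn.trajectory import Trajectory


def _traj(xy, frames=None, dt=1.0):
    xy = np.asarray(xy, float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(0, 0, "red", frames, np.asarray(frames) * dt, xy, dt)


def _brute_force_ta_msd(traj, component, kmax):
    """O(n^2) oracle: loop over every (t, t + tau) pair on the frame grid."""
    grid = traj.on_regular_grid()
    out = []
    for k in range(1, kmax + 1):
        vals = []
        for t in range(len(grid) - k):
            d = grid[t + k] - grid[t]
            if np.any(np.isnan(d)):
                continue
            if component == "r2d":
                vals.append(d[0] ** 2 + d[1] ** 2)
            elif component == "x":
                vals.append(d[0] ** 2)
            else:
                vals.append(d[1] ** 2)
        out.append(np.mean(vals) if vals else np.nan)
    return np.array(out)


class TestTaMsd:
    def test_ballistic_motion_is_quadratic(self):
        s = 3.0
        xy = np.column_stack([s * np.arange(40), np.zeros(40)])
        res = ta_msd(_traj(xy), "x")
        k = np.arange(1, len(res.msd) + 1)
        assert np.allclose(res.msd, (k * s) ** 2)

    def test_stationary_trajectory_is_zero(self):
        res = ta_msd(_traj(np.zeros((30, 2))))
        assert np.allclose(res.msd, 0.0)

    @pytest.mark.parametrize("component", ["r2d", "x", "y"])
    def test_matches_brute_force_oracle(self, component, rng):
        xy = rng.normal(0, 50, size=(60, 2)).cumsum(axis=0)
        res = ta_msd(_traj(xy), component)
        oracle = _brute_force_ta_msd(_traj(xy), component, len(res.msd))
        assert np.allclose(res.msd, oracle, rtol=0, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_gappy_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 40))
        frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
        xy = rng.normal(0, 10, size=(n, 2)).cumsum(axis=0)
        traj = _traj(xy, frames=frames)
        res = ta_msd(traj, "r2d")
        kmax = max(1, (frames[-1] - frames[0] + 1) // 4)
        oracle = _brute_force_ta_msd(traj, "r2d", kmax)
        valid = ~np.isnan(oracle)
        assert np.allclose(res.msd, oracle[valid], rtol=0, atol=1e-9)

    def test_2d_msd_is_sum_of_axis_msds(self, rng):
        xy = rng.normal(0, 30, size=(50, 2)).cumsum(axis=0)
        t = _traj(xy)
        total = ta_msd(t, "r2d").msd
        assert np.allclose(total, ta_msd(t, "x").msd + ta_msd(t, "y").msd)


class TestEaMsd:
    def test_identical_trajectories_equal_displacement_from_start(self):
        xy = np.column_stack([np.arange(20) ** 1.3, np.zeros(20)])
        trajs = [_traj(xy) for _ in range(10)]
        res = ea_msd(trajs, "x")
        expected = (xy[1:, 0] - xy[0, 0]) ** 2
        assert np.allclose(res.msd, expected)

    def test_requires_ten_trajectories(self):
        with pytest.raises(ValueError, match="at least 10"):
            ea_msd([_traj(np.zeros((20, 2)))] * 5)

    def test_unequal_frame_intervals_rejected(self):
        trajs = [_traj(np.zeros((20, 2)), dt=1.0)] * 9 + [_traj(np.zeros((20, 2)), dt=2.0)]
        with pytest.raises(ValueError, match="unequal"):
            ea_msd(trajs)

    def test_fbm_ensemble_and_time_averages_agree(self):
        cfg = SimConfig(alpha_x=0.5, alpha_y=0.5, D_x=1e3, D_y=1e3,
                        n_frames=100, n_traj=500, seed=20)
        trajs = simulate_ensemble(cfg)
        ta = ta_msd_ensemble(trajs)
        ea = ea_msd(trajs)
        for k in range(10):
            curve = ea.curves[:, k]
            se = np.nanstd(curve, ddof=1) / np.sqrt(np.sum(~np.isnan(curve)))
            assert abs(ta.msd[k] - ea.msd[k]) < 3 * se


class TestPowerLawFit:
    @staticmethod
    def _exact(D=4.0, alpha=0.5, n=20, dt=1.0):
        lags = np.arange(1, n + 1) * dt
        return MSDResult("r2d", lags, D * lags**alpha, "time", 1)

    def test_exact_power_law_recovered(self):
        fit = fit_power_law(self._exact(), (2, 10))
        assert fit.D == pytest.approx(4.0, rel=1e-9)
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)

    def test_fit_range_irrelevant_without_noise(self):
        a = fit_power_law(self._exact(), (1, 5))
        b = fit_power_law(self._exact(), (2, 10))
        assert a.alpha == pytest.approx(b.alpha, abs=1e-12)
        assert a.D == pytest.approx(b.D, rel=1e-9)

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            fit_power_law(self._exact(n=3), (1, 10))

    def test_weighted_fit_close_to_ols_on_clean_data(self):
        fit = fit_power_law(
            MSDResult("r2d", np.arange(1, 16.0), 2.0 * np.arange(1, 16.0) ** 0.7,
                      "time", 1, counts=np.arange(15, 0, -1)),
            (1, 10), weighted=True,
        )
        assert fit.alpha == pytest.approx(0.7, abs=1e-9)


class TestVacf:
    def test_theory_closed_form_values(self):
        assert fbm_vacf_theory(0.0, 0.7) == pytest.approx(1.0)
        assert fbm_vacf_theory(1.0, 1.0) == pytest.approx(0.0)
        assert fbm_vacf_theory(1.0, 0.36) == pytest.approx((2**0.36 - 2) / 2, abs=1e-12)
        assert fbm_vacf_theory(1.0, 0.36) == pytest.approx(-0.3583, abs=5e-4)

    def test_fbm_has_negative_minimum_at_delta(self):
        cfg = SimConfig(alpha_x=0.36, alpha_y=0.36, D_x=600, D_y=600,
                        n_frames=120, n_traj=150, seed=21)
        res = vacf(simulate_ensemble(cfg), delta=2)
        xi = res.lags_s / res.delta_s
        j_min = np.nanargmin(res.C_norm[:9])
        assert xi[j_min] == pytest.approx(1.0)
        assert res.C_norm[j_min] < 0
        # quantitative agreement with the closed form at xi = 1
        theory = fbm_vacf_theory(1.0, 0.36)
        assert abs(res.C_norm[j_min] - theory) < 3 * res.C_norm_se[j_min]

    def test_delta_beyond_quarter_span_rejected(self):
        cfg = SimConfig(n_frames=40, n_traj=5, seed=1)
        with pytest.raises(ValueError, match="quarter"):
            vacf(simulate_ensemble(cfg), delta=15)

    def test_collapse_requires_two_deltas(self):
        cfg = SimConfig(n_frames=80, n_traj=20, seed=2)
        res = vacf(simulate_ensemble(cfg), delta=1)
        with pytest.raises(ValueError, match="at least 2"):
            rescale_collapse([res])

    def test_vacf_distinguishes_the_three_mechanisms(self):
        """FBM collapses onto its closed form; CTRW shows no antipersistent
        dip; obstructed diffusion shows at most a weak one — both deviate
        strongly from the FBM prediction."""
        kw = dict(D_x=800, D_y=800, n_frames=120, n_traj=120)
        deltas = (1, 2, 4)

        def collapse(model, seed, **extra):
            trajs = simulate_ensemble(SimConfig(model=model, seed=seed, **kw, **extra))
            vs = [vacf(trajs, m) for m in deltas]
            return vs[0], rescale_collapse(vs, alpha=0.4, xi_max=4.0)

        v_fbm, c_fbm = collapse("fbm", 22, alpha_x=0.4, alpha_y=0.4)
        v_ctrw, c_ctrw = collapse("ctrw", 23, ctrw_beta=0.5)
        v_od, c_od = collapse("od", 24, od_obstacle_density=0.35)
        dip_theory = fbm_vacf_theory(1.0, 0.4)
        assert c_fbm.rms_spread < 0.05 and c_fbm.rms_theory < 0.05
        assert abs(v_ctrw.C_norm[1]) < 4 * v_ctrw.C_norm_se[1]  # no dip
        assert c_ctrw.rms_theory > 2 * c_fbm.rms_theory
        assert v_od.C_norm[1] > dip_theory / 2  # far weaker than viscoelastic
        assert c_od.rms_theory > 2 * c_fbm.rms_theory


class TestErgodicityAndWalkDimension:
    def test_fbm_is_ergodic(self):
        cfg = SimConfig(alpha_x=0.5, alpha_y=0.5, D_x=1e3, D_y=1e3,
                        n_frames=120, n_traj=200, seed=24)
        assert ergodicity_report(simulate_ensemble(cfg)).ergodic

    def test_ctrw_breaks_ergodicity(self):
        cfg = SimConfig(model="ctrw", ctrw_beta=0.5, D_x=1e3, D_y=1e3,
                        n_frames=120, n_traj=200, seed=25)
        report = ergodicity_report(simulate_ensemble(cfg))
        assert not report.ergodic

    @pytest.mark.parametrize(
        "alpha,d_w,compact",
        [(1.0, 2.0, False), (0.5, 4.0, True), (0.36, 2 / 0.36, True)],
    )
    def test_walk_dimension(self, alpha, d_w, compact):
        res = walk_fractal_dimension(alpha)
        assert res.d_w == pytest.approx(d_w)
        assert res.compact is compact

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            walk_fractal_dimension(0.0)
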