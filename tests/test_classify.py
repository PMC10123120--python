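"""Behaviour cascade, mobility filter and position distributions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from locusdyn.classify import (
    ClassifierThresholds,
    class_fractions,
    classify_ice,
    classify_population,
    mobility_filter,
    position_distribution,
)
from locusdyn.config import PopulationConfig
from locusdyn.synthetic.population import add_localization_noise, simulate_population
from locusdyn.track import DistanceSeries, nearest_attb_distance
from locusdyn.trajectory import Trajectory


def _traj(xy, cell_id=0):
    xy = np.asarray(xy, float)
    n = len(xy)
    return Trajectory(cell_id, 2, "green", np.arange(n), np.arange(n) * 1.0, xy, 1.0)


def _dist(d):
    d = np.asarray(d, float)
    return DistanceSeries(0, np.arange(len(d)), np.arange(len(d)) * 1.0, d)


L = 3000.0


class TestCascade:
    def test_tethered_element_is_integrated(self):
        xy = np.tile([0.0, 750.0], (40, 1))
        label = classify_ice(_traj(xy), _dist(np.full(40, 200.0)), L)
        assert label.label == "integrated"
        assert label.median_d_nm == pytest.approx(200.0)

    def test_distance_jump_in_final_half_blocks_integration(self):
        d = np.full(40, 200.0)
        d[30] = 900.0  # 700 nm jump within the final half
        xy = np.zeros((40, 2))
        xy[1] = [0.0, 250.0]  # one mobile step
        assert classify_ice(_traj(xy), _dist(d), L).label == "mobile_local"

    def test_cell_spanning_mobile_element_is_fast(self):
        y = np.linspace(-0.35 * L, 0.35 * L, 30)  # span 70%, steps ~72 nm...
        xy = np.column_stack([np.zeros(30), y])
        xy[5, 0] = 250.0  # plus one large step
        label = classify_ice(_traj(xy), _dist(np.full(30, 800.0)), L)
        assert label.label == "mobile_fast"
        assert label.span_frac == pytest.approx(0.7, abs=1e-9)

    def test_confined_mobile_element_is_local(self):
        xy = np.zeros((30, 2))
        xy[10] = [0.0, 300.0]
        assert classify_ice(_traj(xy), _dist(np.full(30, 800.0)), L).label == "mobile_local"

    def test_quiet_element_is_trapped(self):
        xy = np.cumsum(np.full((30, 2), 5.0), axis=0)
        label = classify_ice(_traj(xy), _dist(np.full(30, 800.0)), L)
        assert label.label == "trapped"
        assert label.rg_nm < 150.0

    def test_missing_distance_series_restricts_to_mobility_classes(self):
        xy = np.tile([0.0, 100.0], (30, 1))
        label = classify_ice(_traj(xy), None, L)
        assert label.restricted
        assert label.label == "trapped"
        assert np.isnan(label.median_d_nm)


class TestPopulationRecovery:
    def test_fractions_recovered_within_binomial_ci(self):
        cfg = PopulationConfig(n_cells=500, seed=61)
        truth = simulate_population(cfg)
        trajs = add_localization_noise(truth.trajectories(), 20.0, seed=62)
        ices = [t for t in trajs if t.channel == "green"]
        by_cell: dict[int, list] = {}
        for t in trajs:
            if t.channel == "red":
                by_cell.setdefault(t.cell_id, []).append(t)
        dists = {i.cell_id: nearest_attb_distance(i, by_cell[i.cell_id]) for i in ices}
        labels = classify_population(ices, dists, truth.cell_lengths())
        frac = class_fractions(labels).set_index("label")
        for name, p in cfg.class_fractions.items():
            ci = 1.96 * np.sqrt(p * (1 - p) / 500)
            assert frac.loc[name, "fraction"] == pytest.approx(p, abs=ci + 1e-9)

    def test_cell_order_does_not_change_counts(self):
        cfg = PopulationConfig(n_cells=60, seed=63)
        truth = simulate_population(cfg)
        ices = [t for t in truth.trajectories() if t.channel == "green"]
        lengths = truth.cell_lengths()
        a = classify_population(ices, {}, lengths)
        b = classify_population(list(reversed(ices)), {}, lengths)
        assert a["label"].value_counts().equals(b["label"].value_counts())


class TestMobilityFilter:
    def test_stationary_excluded_single_step_included(self):
        still = _traj(np.zeros((25, 2)))
        jumpy = _traj(np.vstack([np.zeros((12, 2)), np.tile([0.0, 250.0], (13, 1))]))
        kept = mobility_filter([still, jumpy], 200.0)
        assert kept == [jumpy]

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_step_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trajs = [
            _traj(rng.normal(0, 120, size=(int(rng.integers(5, 40)), 2)).cumsum(axis=0))
            for _ in range(8)
        ]
        kept = mobility_filter(trajs, 200.0)
        for t in trajs:
            biggest = max(
                (float(np.hypot(*(t.xy[i + 1] - t.xy[i]))) for i in range(len(t) - 1)),
                default=0.0,
            )
            assert (t in kept) == (biggest > 200.0)


class TestPositionDistribution:
    def test_all_positions_at_com_give_delta_at_half(self):
        trajs = [_traj(np.zeros((20, 2)), cell_id=0)]
        dist = position_distribution(trajs, pd.Series({0: L}), n_bins=20)
        assert dist.counts.sum() == 20
        assert dist.counts[10] == 20  # the bin containing 0.5
        assert dist.peaks[0] == pytest.approx(0.5, abs=0.05)

    def test_pole_folding_symmetrizes(self):
        xy = np.tile([0.0, 0.2 * L], (10, 1))  # fraction 0.7
        dist = position_distribution([_traj(xy)], pd.Series({0: L}), n_bins=10, fold=True)
        assert dist.n == 20  # each position plus its pole mirror
        assert np.array_equal(dist.counts, dist.counts[::-1])

    def test_out_of_cell_positions_dropped_and_counted(self):
        xy = np.tile([0.0, 0.8 * L], (5, 1))  # fraction 1.3, beyond tolerance
        dist = position_distribution([_traj(xy)], pd.Series({0: L}))
        assert dist.n == 0
        assert dist.n_dropped == 5

    def test_synthetic_population_peaks(self):
        cfg = PopulationConfig(n_cells=250, seed=64)
        truth = simulate_population(cfg)
        trajs = truth.trajectories()
        lengths = truth.cell_lengths()
        attb = position_distribution([t for t in trajs if t.channel == "red"], lengths)
        assert sorted(attb.peaks[:2]) == pytest.approx([0.25, 0.75], abs=0.05)
        mobile = mobility_filter([t for t in trajs if t.channel == "green"], 200.0)
        ice = position_distribution(mobile, lengths)
        assert ice.peaks[0] == pytest.approx(0.5, abs=0.05)
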