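"""Trajectory linking and element-to-target distance series."""

import numpy as np
import pandas as pd
import pytest

from locusdyn.config import PopulationConfig
from locusdyn.synthetic.population import add_localization_noise, simulate_population
from locusdyn.track import link, nearest_attb_distance
from locusdyn.trajectory import Trajectory, trajectories_to_frame


def _detections(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "channel", "frame", "x_nm", "y_nm"])
    df["time_s"] = df["frame"] * 1.0
    return df


class TestLink:
    def test_two_stationary_spots_give_two_full_tracks(self):
        rows = [(0, "red", f, x, 0.0) for f in range(50) for x in (0.0, 1000.0)]
        trajs = link(_detections(rows), min_len=20)
        assert len(trajs) == 2
        assert all(len(t) == 50 for t in trajs)

    def test_single_frame_dropout_is_closed_as_gap(self):
        rows = [(0, "green", f, 0.0, 0.0) for f in range(50) if f != 25]
        trajs = link(_detections(rows), max_gap=2, min_len=20)
        assert len(trajs) == 1
        assert len(trajs[0]) == 49
        assert 25 not in trajs[0].frames

    def test_displacement_above_gate_starts_new_track(self):
        rows = [(0, "green", f, 0.0 if f < 25 else 5000.0, 0.0) for f in range(50)]
        trajs = link(_detections(rows), max_disp=800.0, min_len=20)
        assert len(trajs) == 2

    def test_linking_is_permutation_invariant(self, rng):
        rows = [
            (0, "red", f, x + rng.normal(0, 30), rng.normal(0, 30))
            for f in range(30)
            for x in (0.0, 900.0)
        ]
        base = link(_detections(rows), min_len=10)
        shuffled = _detections(rows).sample(frac=1.0, random_state=3).reset_index(drop=True)
        perm = link(shuffled, min_len=10)
        key = lambda t: (t.cell_id, t.channel, t.frames[0], round(t.xy[0, 0], 6))
        for a, b in zip(sorted(base, key=key), sorted(perm, key=key)):
            assert np.array_equal(a.xy, b.xy)

    def test_hungarian_matches_greedy_on_well_separated_spots(self, rng):
        rows = [
            (0, "red", f, x + rng.normal(0, 40), rng.normal(0, 40))
            for f in range(30)
            for x in (0.0, 1200.0)
        ]
        g = link(_detections(rows), min_len=10, method="greedy")
        h = link(_detections(rows), min_len=10, method="hungarian")
        assert len(g) == len(h) == 2
        for a, b in zip(g, h):
            assert np.array_equal(a.xy, b.xy)

    def test_links_recover_truth_identities(self):
        """On a noisy ground-truth population, >= 99% of per-frame links agree
        with the generating locus identities."""
        cfg = PopulationConfig(n_cells=40, n_frames=60, seed=13)
        truth = simulate_population(cfg)
        noisy = add_localization_noise(truth.trajectories(), 20.0, seed=14)
        det = trajectories_to_frame(noisy)
        linked = link(det, min_len=20)
        # map each linked trajectory to the truth locus with nearest start
        correct = total = 0
        for lt in linked:
            candidates = [
                t for t in noisy if t.cell_id == lt.cell_id and t.channel == lt.channel
            ]
            starts = [np.linalg.norm(t.xy[0] - lt.xy[0]) for t in candidates]
            match = candidates[int(np.argmin(starts))]
            lookup = dict(zip(match.frames.tolist(), match.xy))
            for f, xy in zip(lt.frames.tolist(), lt.xy):
                total += 1
                if f in lookup and np.allclose(lookup[f], xy):
                    correct += 1
        assert total >= 0.95 * 3 * 40 * 60
        assert correct / total >= 0.99


class TestNearestDistance:
    @staticmethod
    def _traj(channel, xy, cell_id=0, locus_id=0):
        n = len(xy)
        return Trajectory(cell_id, locus_id, channel, np.arange(n), np.arange(n) * 1.0,
                          np.asarray(xy, float), 1.0)

    def test_identical_trajectories_give_zero_distance(self):
        xy = np.cumsum(np.ones((30, 2)), axis=0)
        ice = self._traj("green", xy)
        d = nearest_attb_distance(ice, [self._traj("red", xy)])
        assert np.allclose(d.d_nm, 0.0)

    def test_minimum_over_attb_loci(self):
        ice = self._traj("green", np.zeros((5, 2)))
        a1 = self._traj("red", np.tile([0.0, 500.0], (5, 1)), locus_id=0)
        a2 = self._traj("red", np.tile([0.0, -300.0], (5, 1)), locus_id=1)
        d = nearest_attb_distance(ice, [a1, a2])
        assert np.allclose(d.d_nm, 300.0)

    def test_no_shared_cell_raises(self):
        ice = self._traj("green", np.zeros((5, 2)), cell_id=1)
        with pytest.raises(ValueError):
            nearest_attb_distance(ice, [self._traj("red", np.zeros((5, 2)), cell_id=2)])

    def test_tethered_pair_distance_recovers_tether_length(self):
        """Integrated pairs with 20 nm/axis localization noise average to the
        200 nm tether within 15%."""
        cfg = PopulationConfig(n_cells=25, n_frames=90, seed=15,
                               class_fractions={"integrated": 1.0})
        truth = simulate_population(cfg)
        noisy = add_localization_noise(truth.trajectories(), 20.0, seed=16)
        means = []
        for cell_id in range(25):
            cell_trajs = [t for t in noisy if t.cell_id == cell_id]
            ice = next(t for t in cell_trajs if t.channel == "green")
            attbs = [t for t in cell_trajs if t.channel == "red"]
            means.append(nearest_attb_distance(ice, attbs).d_nm.mean())
        assert np.mean(means) == pytest.approx(200.0, rel=0.15)
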