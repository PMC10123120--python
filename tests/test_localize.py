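"""Segmentation, spot detection, sub-pixel fitting and the cell-frame transform."""

import numpy as np
import pytest

from locusdyn.config import PIXEL_SIZE_NM
from locusdyn.localize import (
    CellGeometry,
    SpotFit,
    detect_spots,
    fit_spot_gaussian,
    localize_stack,
    segment_cells,
    to_cell_frame,
)
from locusdyn.synthetic.render import _add_spot, cell_to_lab_px


# --------------------------------------------------------------------------
# segmentation


class TestSegmentation:
    def test_recovers_cells_and_lengths(self, small_population, rendered_field):
        phase = rendered_field.stacks["phase"][0]
        geoms = segment_cells(phase, PIXEL_SIZE_NM)
        assert len(geoms) == len(rendered_field.cells)
        true_by_pos = {
            (round(c.center_px[0]), round(c.center_px[1])): c.length
            for c in rendered_field.cells
        }
        for g in geoms:
            match = min(
                true_by_pos,
                key=lambda p: (p[0] - g.center_of_mass[0]) ** 2 + (p[1] - g.center_of_mass[1]) ** 2,
            )
            assert g.length_nm == pytest.approx(true_by_pos[match], abs=2 * PIXEL_SIZE_NM)
            assert g.length_nm > g.width_nm

    def test_blank_frame_yields_no_cells(self):
        assert segment_cells(np.full((64, 64), 1000.0)) == []

    def test_cell_touching_border_is_excluded(self):
        img = np.full((80, 80), 1000.0)
        img[30:40, 20:60] = 400.0  # interior cell
        img[0:8, 10:50] = 400.0  # bisected by the frame edge
        geoms = segment_cells(img, PIXEL_SIZE_NM)
        assert len(geoms) == 1
        assert 30 < geoms[0].center_of_mass[1] < 40


# --------------------------------------------------------------------------
# detection


class TestDetection:
    @staticmethod
    def _geometry_with_mask(shape=(64, 64)):
        mask = np.zeros(shape, bool)
        mask[20:44, 10:54] = True
        centerline = np.array([[12.0, 32.0], [52.0, 32.0]])
        return CellGeometry(
            cell_id=0, boundary=np.array([[10, 20], [53, 20], [53, 43], [10, 43]]),
            center_of_mass=(32.0, 32.0), centerline=centerline,
            length_nm=42 * PIXEL_SIZE_NM, width_nm=24 * PIXEL_SIZE_NM, mask=mask,
        )

    def test_single_spot_gives_single_cluster(self, rng):
        geom = self._geometry_with_mask()
        img = rng.poisson(100.0, (64, 64)).astype(float)
        _add_spot(img, 30.0, 30.0, 1.2, 1500.0)
        assert len(detect_spots(img, geom)) == 1

    def test_uniform_background_gives_no_clusters(self, rng):
        geom = self._geometry_with_mask()
        hits = sum(
            len(detect_spots(rng.poisson(100.0, (64, 64)).astype(float), geom))
            for _ in range(20)
        )
        assert hits <= 1  # false-positive rate well below one per cell

    def test_two_separated_spots_give_two_clusters(self, rng):
        geom = self._geometry_with_mask()
        img = rng.poisson(100.0, (64, 64)).astype(float)
        _add_spot(img, 25.0, 30.0, 1.2, 1500.0)
        _add_spot(img, 35.0, 30.0, 1.2, 1500.0)  # 10 px apart
        assert len(detect_spots(img, geom)) == 2

    def test_oversized_cluster_rejected(self):
        geom = self._geometry_with_mask()
        img = np.full((64, 64), 100.0)
        img[geom.mask] = 10_000.0  # whole cell above threshold
        assert detect_spots(img, geom, abs_threshold=5000.0) == []


# --------------------------------------------------------------------------
# Gaussian fitting


class TestGaussianFit:
    def test_noiseless_subpixel_accuracy(self):
        img = np.zeros((21, 21))
        _add_spot(img, 10.30, 9.70, 1.2, 1e5)
        fit = fit_spot_gaussian(img, (10, 10))
        assert fit.col == pytest.approx(10.30, abs=0.05)
        assert fit.row == pytest.approx(9.70, abs=0.05)

    def test_offset_equals_added_constant(self):
        img = np.full((15, 15), 37.0)
        _add_spot(img, 7.0, 7.0, 1.2, 2000.0)
        fit = fit_spot_gaussian(img, (7, 7))
        assert fit.offset == pytest.approx(37.0, abs=0.5)
        assert fit.col == pytest.approx(7.0, abs=1e-3)

    def test_monte_carlo_precision_below_quarter_pixel(self, rng):
        errs = []
        for _ in range(300):
            img = np.zeros((15, 15))
            col, row = 7 + rng.uniform(-0.5, 0.5), 7 + rng.uniform(-0.5, 0.5)
            _add_spot(img, col, row, 130.0 / PIXEL_SIZE_NM, 1500.0)
            noisy = rng.poisson(img + 100.0) + rng.standard_normal(img.shape) * 2.0
            fit = fit_spot_gaussian(np.rint(noisy), (7, 7))
            if fit is not None:
                errs.append((fit.col - col, fit.row - row))
        errs = np.array(errs)
        assert len(errs) > 280
        assert errs.std(axis=0).max() < 0.25  # px, ~27 nm

    def test_window_leaving_frame_drops_spot(self):
        assert fit_spot_gaussian(np.zeros((11, 11)), (1, 5)) is None


# --------------------------------------------------------------------------
# cell-frame transform


def _straight_geometry():
    centerline = np.array([[5.0, 20.0], [35.0, 20.0]])
    return CellGeometry(
        cell_id=0, boundary=np.empty((0, 2)), center_of_mass=(20.0, 20.0),
        centerline=centerline, length_nm=30 * PIXEL_SIZE_NM, width_nm=8 * PIXEL_SIZE_NM,
    )


def _spot(col, row):
    return SpotFit("green", 0, col, row, 1.0, 1.2, 0.0, 0.0)


class TestCellFrame:
    def test_centerline_midpoint_maps_to_origin(self):
        pos = to_cell_frame(_spot(20.0, 20.0), _straight_geometry())
        assert pos.x_nm == pytest.approx(0.0, abs=1e-9)
        assert pos.y_nm == pytest.approx(0.0, abs=1e-9)

    def test_horizontal_cell_offsets_scale_by_pixel_size(self):
        # 2 px above the centerline, 10 px right of the center of mass
        pos = to_cell_frame(_spot(30.0, 18.0), _straight_geometry())
        assert pos.x_nm == pytest.approx(2 * PIXEL_SIZE_NM)
        assert pos.y_nm == pytest.approx(10 * PIXEL_SIZE_NM)

    def test_projection_beyond_end_is_clamped_and_flagged(self):
        pos = to_cell_frame(_spot(45.0, 20.0), _straight_geometry())
        assert pos.clamped
        assert pos.y_nm == pytest.approx(15 * PIXEL_SIZE_NM)

    def test_curved_cell_norm_matches_euclidean_distance(self):
        # gently curved centerline: |(x, y)| approximates the straight-line
        # distance to the center of mass for small curvature
        radius = 120.0
        phi = np.linspace(-0.15, 0.15, 61)
        centerline = np.column_stack([radius * np.sin(phi) + 50, 50 + radius * (1 - np.cos(phi))])
        geom = CellGeometry(
            cell_id=0, boundary=np.empty((0, 2)),
            center_of_mass=tuple(centerline[30]), centerline=centerline,
            length_nm=2 * 0.15 * radius * PIXEL_SIZE_NM, width_nm=5 * PIXEL_SIZE_NM,
        )
        p = centerline[45] + np.array([0.4, -1.1])
        pos = to_cell_frame(_spot(*p), geom)
        euclid = np.linalg.norm(p - centerline[30]) * PIXEL_SIZE_NM
        assert np.hypot(pos.x_nm, pos.y_nm) == pytest.approx(euclid, rel=0.05)

    def test_transform_invariant_under_rigid_motion(self, rng):
        """Rotating/translating spot and geometry together leaves (x, y)
        unchanged within 0.05 px."""
        geom = _straight_geometry()
        p = np.array([27.3, 18.4])
        ref = to_cell_frame(_spot(*p), geom)
        for _ in range(10):
            phi = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-30, 30, size=2)
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            centerline = geom.centerline @ R.T + shift
            moved = CellGeometry(
                cell_id=0, boundary=np.empty((0, 2)),
                center_of_mass=tuple(np.asarray(geom.center_of_mass) @ R.T + shift),
                centerline=centerline, length_nm=geom.length_nm, width_nm=geom.width_nm,
            )
            pos = to_cell_frame(_spot(*(p @ R.T + shift)), moved)
            assert pos.x_nm == pytest.approx(ref.x_nm, abs=0.05 * PIXEL_SIZE_NM)
            assert pos.y_nm == pytest.approx(ref.y_nm, abs=0.05 * PIXEL_SIZE_NM)

    def test_image_level_quarter_turn_consistency(self, noiseless_population, noiseless_field):
        """Recomputing everything on a 90-deg-rotated frame reproduces the
        cell-frame coordinates up to the pole ambiguity and the (sub-pixel)
        reproducibility of the re-estimated centerline."""
        cfg = noiseless_population.config
        stacks = noiseless_field.stacks
        rotated = {ch: np.rot90(s, axes=(1, 2)).copy() for ch, s in stacks.items()}
        det = localize_stack(stacks, cfg.pixel_size, refit_geometry=False)
        det_rot = localize_stack(rotated, cfg.pixel_size, refit_geometry=False)
        assert len(det) == len(det_rot) > 0
        a = det.sort_values(["frame", "channel", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        b = det_rot.sort_values(["frame", "channel", "x_nm"])[["x_nm", "y_nm"]].to_numpy()
        tol = 0.5 * PIXEL_SIZE_NM

        def matches(u, v):
            return any(
                np.allclose(u, [s * v[0], s * v[1]], atol=tol) for s in (1, -1)
            )

        for u in a:
            assert any(matches(u, v) for v in b)


# --------------------------------------------------------------------------
# end-to-end stack localization


def test_end_to_end_rmse_below_25nm(small_population, rendered_field):
    cfg = small_population.config
    det = localize_stack(rendered_field.stacks, cfg.pixel_size, dt=cfg.dt)
    geoms = segment_cells(rendered_field.stacks["phase"][0], cfg.pixel_size)
    gmap = {}
    for g in geoms:
        d = [
            np.hypot(g.center_of_mass[0] - c.center_px[0], g.center_of_mass[1] - c.center_px[1])
            for c in rendered_field.cells
        ]
        gmap[g.cell_id] = rendered_field.cells[int(np.argmin(d))]
    errs = []
    for _, row in det.iterrows():
        cell = gmap[row.cell_id]
        best = None
        for traj in cell.trajectories:
            if traj.channel != row.channel:
                continue
            lab = cell_to_lab_px(cell, traj.xy[int(row.frame)], cfg.pixel_size)[0]
            e = np.hypot(lab[0] - row.x_px, lab[1] - row.y_px) * cfg.pixel_size
            best = e if best is None else min(best, e)
        errs.append(best)
    errs = np.array(errs)
    assert len(errs) >= 0.9 * len(rendered_field.cells) * 3 * cfg.n_frames
    assert np.sqrt(np.mean(errs**2)) < 25.0
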