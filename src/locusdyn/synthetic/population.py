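"""Whole-population generator with known ground truth.

Each synthetic transconjugant is a stadium-shaped cell carrying two attB
loci — anisotropic FBM anchored near 1/4 and 3/4 of the long axis — and one
element (ICE) trajectory drawn from a behaviour-class mixture:

* ``integrated``  — rides on one attB locus at a tether offset whose length
  fluctuates around the configured tether distance (~200 nm);
* ``mobile_fast`` — episodic cell-spanning motion: a slow longitudinal
  sweep across ~70% of the cell length superposed with FBM, producing
  frame-to-frame steps well above 200 nm;
* ``mobile_local`` — intermediate-mobility FBM confined near mid-cell;
* ``trapped``     — low-mobility FBM pinned near a pole, radius of gyration
  below 150 nm.

All positions are kept inside the cell by reflecting at an interior margin;
the defaults keep trajectories far enough from the boundary that no MSD
plateau is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from locusdyn._rng import substream
from locusdyn.config import BEHAVIOR_LABELS, PopulationConfig
from locusdyn.synthetic.fgn import simulate_fbm_path, simulate_fgn_axis
from locusdyn.trajectory import Trajectory, trajectories_to_frame

__all__ = ["CellTruth", "GroundTruth", "simulate_population", "add_localization_noise"]

#: margin (nm) between any trajectory and the cell boundary
BOUNDARY_MARGIN_NM = 150.0
#: attB confinement half-width as a fraction of cell length
ATTB_CONFINE_FRAC = 0.08
#: fast-mobile longitudinal drive: per-frame step scale (nm) and AR(1)
#: relaxation toward mid-cell per frame
FAST_STEP_NM = 250.0
FAST_RELAX = 0.85
#: apparent diffusion coefficients of the element by mobility regime,
#: nm^2/s^alpha (assumed: the source quantifies these only graphically)
ICE_D_FAST = 4000.0
ICE_D_LOCAL = 7800.0
ICE_D_TRAPPED = 500.0
#: locally-mobile confinement half-width as a fraction of cell length
LOCAL_CONFINE_FRAC = 0.08
#: trapped confinement radius, nm
TRAPPED_CONFINE_NM = 100.0
#: per-frame random-walk scale of the integrated tether angle, rad
TETHER_ANGLE_STEP = 0.3


@dataclass
class CellTruth:
    """Ground truth of one synthetic cell."""

    cell_id: int
    length: float  # nm
    width: float  # nm
    label: str
    attB_anchors: tuple[float, ...]  # longitudinal positions, nm from COM
    trajectories: list[Trajectory]  # two attB ("red") then one ICE ("green")
    center_px: tuple[float, float]  # (col, row) placement in its field of view
    theta: float  # orientation of the long axis, rad
    field_id: int  # which rendered field of view the cell sits in
    alphas: dict = field(default_factory=dict)  # generating exponents per axis
    Ds: dict = field(default_factory=dict)  # generating diffusion coefficients


@dataclass
class GroundTruth:
    """A simulated population plus everything needed to render and to score."""

    config: PopulationConfig
    cells: list[CellTruth]

    @property
    def n_fields(self) -> int:
        return 1 + max(c.field_id for c in self.cells)

    def trajectories(self) -> list[Trajectory]:
        return [t for c in self.cells for t in c.trajectories]

    def labels(self) -> pd.Series:
        return pd.Series({c.cell_id: c.label for c in self.cells}, name="label")

    def cell_lengths(self) -> pd.Series:
        return pd.Series({c.cell_id: c.length for c in self.cells}, name="length_nm")

    def to_frame(self) -> pd.DataFrame:
        df = trajectories_to_frame(self.trajectories())
        labels = self.labels()
        df["label"] = df["cell_id"].map(labels)
        return df


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by specular reflection at both walls."""
    span = hi - lo
    if span <= 0:
        return np.full_like(v, 0.5 * (lo + hi))
    u = np.mod(v - lo, 2.0 * span)
    return lo + np.where(u > span, 2.0 * span - u, u)


def _exact_label_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment so realized counts match the mixture."""
    labels = [l for l in BEHAVIOR_LABELS if fractions.get(l, 0.0) > 0]
    raw = {l: fractions[l] * n for l in labels}
    counts = {l: int(np.floor(raw[l])) for l in labels}
    short = n - sum(counts.values())
    for l in sorted(labels, key=lambda l: raw[l] - np.floor(raw[l]), reverse=True)[:short]:
        counts[l] += 1
    return counts


def _confined_fbm(
    alpha: float,
    D: float,
    cfg: PopulationConfig,
    anchor: float,
    halfwidth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    path = anchor + simulate_fbm_path(alpha, D, cfg.dt, cfg.n_frames, rng)
    return _reflect(path, anchor - halfwidth, anchor + halfwidth)


def _attb_trajectory(
    cfg: PopulationConfig, anchor_y: float, L: float, rng: np.random.Generator
) -> np.ndarray:
    half_w = cfg.cell_width / 2.0 - BOUNDARY_MARGIN_NM
    x = _confined_fbm(cfg.attB_alpha_x, cfg.attB_D_x, cfg, 0.0, half_w, rng)
    y = _confined_fbm(cfg.attB_alpha_y, cfg.attB_D_y, cfg, anchor_y, ATTB_CONFINE_FRAC * L, rng)
    return np.column_stack([x, y])


def _ice_xy(
    label: str,
    cfg: PopulationConfig,
    L: float,
    attb_xy: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    half_w = cfg.cell_width / 2.0 - BOUNDARY_MARGIN_NM
    n = cfg.n_frames
    if label == "integrated":
        target = attb_xy[rng.integers(len(attb_xy))]
        phi = rng.uniform(0, 2 * np.pi) + np.cumsum(
            rng.standard_normal(n) * TETHER_ANGLE_STEP
        )
        ell = np.clip(
            rng.normal(cfg.tether_distance, 0.15 * cfg.tether_distance, size=n), 0.0, None
        )
        xy = target + np.column_stack([ell * np.cos(phi), ell * np.sin(phi)])
    elif label == "mobile_fast":
        # cell-spanning excursions with a mid-cell-peaked position
        # distribution: antipersistent fGn steps relaxed toward mid-cell
        D_fast_y = FAST_STEP_NM**2 / cfg.dt**cfg.attB_alpha_y
        eps = simulate_fgn_axis(cfg.attB_alpha_y, D_fast_y, cfg.dt, n, rng)
        y = np.empty(n)
        y[0] = 0.0
        for k in range(1, n):
            y[k] = FAST_RELAX * y[k - 1] + eps[k - 1]
        # normalize the excursion so the class is cell-spanning by construction
        span = y.max() - y.min()
        if span > 0:
            y = (y - y.mean()) * (rng.uniform(0.55, 0.75) * L / span)
        x = _confined_fbm(cfg.attB_alpha_x, ICE_D_FAST, cfg, 0.0, half_w, rng)
        xy = np.column_stack([x, y])
    elif label == "mobile_local":
        x = _confined_fbm(cfg.attB_alpha_x, ICE_D_LOCAL, cfg, 0.0, half_w, rng)
        y = _confined_fbm(cfg.attB_alpha_y, ICE_D_LOCAL, cfg, 0.0, LOCAL_CONFINE_FRAC * L, rng)
        xy = np.column_stack([x, y])
    elif label == "trapped":
        # quiescent near a pole, clear of the attB home regions at 1/4 and 3/4
        pole = rng.choice([-1.0, 1.0]) * min(
            rng.uniform(0.40, 0.45) * L, L / 2 - BOUNDARY_MARGIN_NM - TRAPPED_CONFINE_NM
        )
        x = _confined_fbm(cfg.attB_alpha_x, ICE_D_TRAPPED, cfg, 0.0, TRAPPED_CONFINE_NM, rng)
        y = _confined_fbm(cfg.attB_alpha_y, ICE_D_TRAPPED, cfg, pole, TRAPPED_CONFINE_NM, rng)
        xy = np.column_stack([x, y])
    else:  # pragma: no cover - guarded by PopulationConfig validation
        raise ValueError(f"unknown behaviour label {label!r}")
    # final clip into the interior box (inside the stadium at this margin)
    xy[:, 0] = _reflect(xy[:, 0], -half_w, half_w)
    xy[:, 1] = _reflect(xy[:, 1], -(L / 2 - BOUNDARY_MARGIN_NM), L / 2 - BOUNDARY_MARGIN_NM)
    return xy


def _place_cells(lengths: np.ndarray, cfg: PopulationConfig, rng: np.random.Generator):
    """Assign non-overlapping grid slots (and fields of view) to all cells."""
    h, w = cfg.image_shape
    pitch_px = float(lengths.max() + 3 * cfg.cell_width) / cfg.pixel_size
    # margin keeps the whole stadium (reach = L/2 + width) plus jitter in frame
    margin_px = (lengths.max() / 2 + 1.5 * cfg.cell_width) / cfg.pixel_size + 2
    n_cols = max(1, int((w - 2 * margin_px) // pitch_px) + 1)
    n_rows = max(1, int((h - 2 * margin_px) // pitch_px) + 1)
    per_field = n_cols * n_rows
    placements = []
    for i in range(len(lengths)):
        slot = i % per_field
        r, c = divmod(slot, n_cols)
        col = margin_px + c * pitch_px + 0.1 * pitch_px * (rng.uniform() - 0.5)
        row = margin_px + r * pitch_px + 0.1 * pitch_px * (rng.uniform() - 0.5)
        theta = rng.uniform(0, np.pi)
        placements.append(((col, row), theta, i // per_field))
    return placements


def simulate_population(cfg: PopulationConfig) -> GroundTruth:
    """Simulate a population of transconjugant cells with known labels."""
    rng0 = substream(cfg.seed, "simulate")
    counts = _exact_label_counts(dict(cfg.class_fractions), cfg.n_cells)
    labels = np.array([l for l, c in counts.items() for _ in range(c)])
    rng0.shuffle(labels)
    lengths = np.clip(
        rng0.normal(cfg.cell_length_mean, cfg.cell_length_sd, size=cfg.n_cells),
        max(1.5 * cfg.cell_width, 0.6 * cfg.cell_length_mean),
        1.6 * cfg.cell_length_mean,
    )
    placements = _place_cells(lengths, cfg, rng0)

    cells = []
    for i in range(cfg.n_cells):
        rng = substream(cfg.seed, "simulate", i + 1)
        L = float(lengths[i])
        anchors = tuple((f - 0.5) * L for f in cfg.attB_longitudinal_positions)
        attb_xy = [_attb_trajectory(cfg, a, L, rng) for a in anchors]
        ice_xy = _ice_xy(str(labels[i]), cfg, L, attb_xy, rng)
        frames = np.arange(cfg.n_frames)
        times = frames * cfg.dt
        trajs = [
            Trajectory(i, j, "red", frames, times, xy, cfg.dt)
            for j, xy in enumerate(attb_xy)
        ]
        trajs.append(Trajectory(i, len(attb_xy), "green", frames, times, ice_xy, cfg.dt))
        center, theta, field_id = placements[i]
        cells.append(
            CellTruth(
                cell_id=i,
                length=L,
                width=cfg.cell_width,
                label=str(labels[i]),
                attB_anchors=anchors,
                trajectories=trajs,
                center_px=center,
                theta=theta,
                field_id=field_id,
                alphas={"attB_x": cfg.attB_alpha_x, "attB_y": cfg.attB_alpha_y},
                Ds={"attB_x": cfg.attB_D_x, "attB_y": cfg.attB_D_y},
            )
        )
    return GroundTruth(config=cfg, cells=cells)


def tethered_pair_cell(cfg: PopulationConfig, wobble_nm: float = 15.0) -> GroundTruth:
    """One cell holding a red locus and a green locus at a fixed separation.

    The red (target) locus wobbles gently; the green (element) locus sits at
    exactly ``cfg.tether_distance`` from it with an independent random
    in-plane orientation each frame.  Used to calibrate the measured
    separation of integrated pairs through rendering and localization.
    """
    rng = substream(cfg.seed, "simulate", 0)
    n = cfg.n_frames
    red = np.column_stack(
        [rng.standard_normal(n) * wobble_nm, 300.0 + rng.standard_normal(n) * wobble_nm]
    )
    phi = rng.uniform(0, 2 * np.pi, size=n)
    green = red + cfg.tether_distance * np.column_stack([np.cos(phi), np.sin(phi)])
    frames = np.arange(n)
    times = frames * cfg.dt
    L = cfg.cell_length_mean
    h, w = cfg.image_shape
    cell = CellTruth(
        cell_id=0,
        length=L,
        width=cfg.cell_width,
        label="integrated",
        attB_anchors=(300.0,),
        trajectories=[
            Trajectory(0, 0, "red", frames, times, red, cfg.dt),
            Trajectory(0, 1, "green", frames, times, green, cfg.dt),
        ],
        center_px=(w / 2.0, h / 2.0),
        theta=rng.uniform(0, np.pi),
        field_id=0,
    )
    return GroundTruth(config=cfg, cells=[cell])


def add_localization_noise(
    trajs: list[Trajectory], sigma_nm: float, seed: int = 0
) -> list[Trajectory]:
    """Return copies with i.i.d. Gaussian localization error per axis."""
    out = []
    for k, t in enumerate(trajs):
        rng = substream(seed, "noise", k)
        xy = t.xy + rng.standard_normal(t.xy.shape) * sigma_nm
        out.append(
            Trajectory(t.cell_id, t.locus_id, t.channel, t.frames, t.times, xy, t.dt)
        )
    return out
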