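"""Diffraction-limited two-channel microscopy renderer.

Produces, per frame, a phase-contrast-like channel (dark stadium-shaped
cells on a bright background with Gaussian noise) and two fluorescence
channels (green = element spots, red = attB spots).  Each spot is an
integrated symmetric 2D Gaussian of width ``psf_sigma`` whose photon count
equals the photon budget; pixel values then receive Poisson shot noise on
signal-plus-background, Gaussian read noise and a constant camera offset.
Rendering is byte-deterministic given the population seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from locusdyn._rng import substream
from locusdyn.synthetic.population import CellTruth, GroundTruth

log = logging.getLogger(__name__)

__all__ = ["RenderResult", "render_frame", "render_stack", "write_stacks", "cell_to_lab_px"]

#: camera offset added to every fluorescence pixel, counts
CAMERA_OFFSET = 100.0
#: phase channel: background and cell-interior intensity, plus noise sigma
PHASE_BACKGROUND = 1000.0
PHASE_CELL = 400.0
PHASE_NOISE_SD = 10.0
#: stand-in amplitude for an infinite photon budget (noiseless rendering)
_NOISELESS_AMPLITUDE = 1e5

CHANNELS = ("phase", "green", "red")


@dataclass
class RenderResult:
    """Rendered stacks for one field of view plus the cells they contain."""

    stacks: dict[str, np.ndarray]  # channel -> (n_frames, H, W) uint16
    cells: list[CellTruth]  # cells actually rendered (edge cells dropped)
    field_id: int


def cell_to_lab_px(cell: CellTruth, xy_nm: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map cell-frame (x transversal, y longitudinal) nm to lab (col, row) px."""
    xy_nm = np.atleast_2d(xy_nm)
    cos_t, sin_t = np.cos(cell.theta), np.sin(cell.theta)
    col = cell.center_px[0] + (xy_nm[:, 1] * cos_t - xy_nm[:, 0] * sin_t) / pixel_size
    row = cell.center_px[1] + (xy_nm[:, 1] * sin_t + xy_nm[:, 0] * cos_t) / pixel_size
    return np.column_stack([col, row])


def _stadium_mask(cell: CellTruth, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
    """Boolean stadium (capsule) footprint of one cell on the pixel grid."""
    h, w = shape
    half_axis = (cell.length - cell.width) / 2.0  # centerline half-length, nm
    radius = cell.width / 2.0
    pad = int(np.ceil((cell.length / 2.0 + radius) / pixel_size)) + 2
    c0, r0 = cell.center_px
    cols = np.arange(max(0, int(c0) - pad), min(w, int(c0) + pad + 1))
    rows = np.arange(max(0, int(r0) - pad), min(h, int(r0) + pad + 1))
    if len(cols) == 0 or len(rows) == 0:
        return np.zeros(shape, bool)
    cc, rr = np.meshgrid(cols, rows)
    # lab px -> cell frame nm
    dcol = (cc - c0) * pixel_size
    drow = (rr - r0) * pixel_size
    cos_t, sin_t = np.cos(cell.theta), np.sin(cell.theta)
    y = dcol * cos_t + drow * sin_t
    x = -dcol * sin_t + drow * cos_t
    yc = np.clip(y, -half_axis, half_axis)
    inside = (y - yc) ** 2 + x**2 <= radius**2
    mask = np.zeros(shape, bool)
    mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] = inside
    return mask


def _add_spot(img: np.ndarray, col: float, row: float, sigma_px: float, photons: float) -> None:
    """Accumulate an integrated 2D Gaussian spot (total ``photons``) in place."""
    h, w = img.shape
    rad = int(np.ceil(6 * sigma_px)) + 1
    c0, r0 = int(round(col)), int(round(row))
    cols = np.arange(max(0, c0 - rad), min(w, c0 + rad + 1))
    rows = np.arange(max(0, r0 - rad), min(h, r0 + rad + 1))
    if len(cols) == 0 or len(rows) == 0:
        return
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((cols + 0.5 - col) / s) - erf((cols - 0.5 - col) / s))
    fy = 0.5 * (erf((rows + 0.5 - row) / s) - erf((rows - 0.5 - row) / s))
    img[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1] += photons * np.outer(fy, fx)


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def _cells_in_frame(truth: GroundTruth, field_id: int) -> list[CellTruth]:
    h, w = truth.config.image_shape
    keep = []
    for cell in truth.cells:
        if cell.field_id != field_id:
            continue
        reach = (cell.length / 2.0 + cell.width) / truth.config.pixel_size
        c0, r0 = cell.center_px
        if c0 - reach < 0 or r0 - reach < 0 or c0 + reach >= w or r0 + reach >= h:
            log.warning("cell %d overlaps the frame edge; excluded", cell.cell_id)
            continue
        keep.append(cell)
    return keep


def render_frame(
    truth: GroundTruth, frame: int, field_id: int = 0, cells: list[CellTruth] | None = None
) -> dict[str, np.ndarray]:
    """Render the three channels of one frame of one field of view."""
    cfg = truth.config
    if cells is None:
        cells = _cells_in_frame(truth, field_id)
    shape = cfg.image_shape
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    noiseless = not np.isfinite(cfg.photon_budget)
    photons = _NOISELESS_AMPLITUDE if noiseless else cfg.photon_budget

    out: dict[str, np.ndarray] = {}
    phase = np.full(shape, PHASE_BACKGROUND)
    for cell in cells:
        phase[_stadium_mask(cell, shape, cfg.pixel_size)] = PHASE_CELL
    phase = gaussian_filter(phase, 1.0)
    rng = substream(cfg.seed, "render", field_id, frame, 0)
    phase = phase + rng.standard_normal(shape) * PHASE_NOISE_SD
    out["phase"] = _to_uint16(phase)

    for ch_idx, channel in enumerate(("green", "red"), start=1):
        img = np.zeros(shape)
        for cell in cells:
            for traj in cell.trajectories:
                if traj.channel != channel:
                    continue
                where = np.flatnonzero(traj.frames == frame)
                if len(where) == 0:
                    continue
                col, row = cell_to_lab_px(cell, traj.xy[where[0]], cfg.pixel_size)[0]
                _add_spot(img, col, row, sigma_px, photons)
        signal = img + cfg.background
        rng = substream(cfg.seed, "render", field_id, frame, ch_idx)
        if not noiseless:
            signal = rng.poisson(signal).astype(float)
        if cfg.read_noise > 0:
            signal = signal + rng.standard_normal(shape) * cfg.read_noise
        out[channel] = _to_uint16(signal + CAMERA_OFFSET)
    return out


def render_stack(truth: GroundTruth, field_id: int = 0) -> RenderResult:
    """Render all frames of one field of view."""
    cfg = truth.config
    cells = _cells_in_frame(truth, field_id)
    stacks = {ch: np.empty((cfg.n_frames, *cfg.image_shape), np.uint16) for ch in CHANNELS}
    for frame in range(cfg.n_frames):
        imgs = render_frame(truth, frame, field_id, cells)
        for ch in CHANNELS:
            stacks[ch][frame] = imgs[ch]
    return RenderResult(stacks=stacks, cells=cells, field_id=field_id)


def write_stacks(
    result: RenderResult,
    truth: GroundTruth,
    out_dir: str | Path,
    interleaved: bool = False,
) -> dict[str, Path]:
    """Write TIFF stack(s) plus the ground-truth tables for one field.

    ``interleaved=True`` writes a single (frames, channels, H, W) stack;
    otherwise one multi-page TIFF per channel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"field{result.field_id:03d}"
    paths: dict[str, Path] = {}
    if interleaved:
        arr = np.stack([result.stacks[ch] for ch in CHANNELS], axis=1)
        paths["stack"] = out_dir / f"{tag}.tif"
        tifffile.imwrite(paths["stack"], arr, metadata={"axes": "TCYX"})
    else:
        for ch in CHANNELS:
            paths[ch] = out_dir / f"{tag}_{ch}.tif"
            tifffile.imwrite(paths[ch], result.stacks[ch])

    rendered_ids = {c.cell_id for c in result.cells}
    df = truth.to_frame()
    df = df[df["cell_id"].isin(rendered_ids)]
    paths["truth"] = out_dir / f"{tag}_truth.csv"
    df.to_csv(paths["truth"], index=False)

    cells_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in result.cells],
            "field_id": result.field_id,
            "center_col_px": [c.center_px[0] for c in result.cells],
            "center_row_px": [c.center_px[1] for c in result.cells],
            "theta_rad": [c.theta for c in result.cells],
            "length_nm": [c.length for c in result.cells],
            "width_nm": [c.width for c in result.cells],
            "label": [c.label for c in result.cells],
        }
    )
    paths["cells"] = out_dir / f"{tag}_cells.csv"
    cells_df.to_csv(paths["cells"], index=False)
    return paths
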