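"""Sub-pixel spot localization in cell-frame coordinates.

The stages mirror standard single-particle-tracking practice in rod-shaped
bacteria: segment cells in the phase-contrast channel, derive each cell's
center of mass and centerline, detect fluorescent pixel clusters above a
robust per-cell threshold, fit each spot with a symmetric 2D Gaussian plus
a constant, and express the fitted center as (x, y): the signed transversal
distance to the centerline and the signed longitudinal arc-length position
relative to the projection of the center of mass.

Pixel convention: 0-based indices with the pixel center at integer
coordinates; lab positions are (col, row) in px, cell-frame output in nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep
from scipy.ndimage import binary_fill_holes, distance_transform_edt
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import closing, disk, skeletonize
from skimage.segmentation import clear_border

from locusdyn.config import PIXEL_SIZE_NM

log = logging.getLogger(__name__)

__all__ = [
    "CellGeometry",
    "SpotFit",
    "CellFramePosition",
    "segment_cells",
    "detect_spots",
    "fit_spot_gaussian",
    "to_cell_frame",
    "localize_stack",
    "DETECTION_COLUMNS",
]

DETECTION_COLUMNS = [
    "cell_id",
    "channel",
    "frame",
    "x_px",
    "y_px",
    "x_nm",
    "y_nm",
    "amplitude",
    "sigma_px",
    "offset",
    "residual",
]

#: Gaussian-fit window half-size (window is 2*half+1 square), px
FIT_WINDOW_HALF = 3
#: admissible Gaussian widths, px
SIGMA_BOUNDS = (0.5, 5.0)
#: default robust-threshold multiplier (median + k * scaled MAD)
THRESHOLD_K = 5.0
#: maximum spots per channel per cell; more indicates a segmentation or
#: biology violation and drops the cell for that frame
MAX_SPOTS_PER_CHANNEL = 2


@dataclass
class CellGeometry:
    """Boundary, center of mass and centerline of one segmented cell."""

    cell_id: int
    boundary: np.ndarray  # (n, 2) closed polygon, (col, row) px
    center_of_mass: tuple[float, float]  # (col, row) px
    centerline: np.ndarray  # (m, 2) ordered points pole-to-pole, (col, row) px
    length_nm: float
    width_nm: float
    mask: np.ndarray | None = None  # full-frame boolean mask
    _arclen: np.ndarray = field(default=None, repr=False)  # cumulative, px
    _com_s: float = field(default=None, repr=False)  # COM foot arc length, px

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, float)
        seg = np.diff(self.centerline, axis=0)
        self._arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
        self._com_s, _, _ = _project_on_polyline(
            np.asarray(self.center_of_mass, float), self.centerline, self._arclen
        )

    def oriented_like(self, ref: "CellGeometry") -> "CellGeometry":
        """Flip the centerline direction, if needed, to match ``ref``'s poles."""
        same = np.linalg.norm(self.centerline[0] - ref.centerline[0])
        flipped = np.linalg.norm(self.centerline[0] - ref.centerline[-1])
        if flipped < same:
            return CellGeometry(
                cell_id=self.cell_id,
                boundary=self.boundary,
                center_of_mass=self.center_of_mass,
                centerline=self.centerline[::-1].copy(),
                length_nm=self.length_nm,
                width_nm=self.width_nm,
                mask=self.mask,
            )
        return self


@dataclass
class SpotFit:
    """Sub-pixel Gaussian-plus-constant fit of one fluorescent spot."""

    channel: str
    frame: int
    col: float  # sub-pixel lab column
    row: float  # sub-pixel lab row
    amplitude: float
    sigma: float  # px
    offset: float  # fitted constant background
    residual: float  # residual 2-norm
    cell_id: int = -1


@dataclass
class CellFramePosition:
    """Cell-frame coordinates of one localized spot, nm."""

    x_nm: float  # signed transversal distance to the centerline
    y_nm: float  # signed longitudinal arc-length position from the COM foot
    clamped: bool = False  # foot point fell beyond a centerline end


# --------------------------------------------------------------------------
# segmentation and centerline


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray | None:
    """Order skeleton pixels along the longest geodesic path (col, row)."""
    pts = np.argwhere(skel)  # (row, col)
    if len(pts) < 2:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    ends = [n for n in g.nodes if g.degree(n) <= 1]
    if len(ends) < 2:
        ends = list(g.nodes)
    best, best_len = None, -1.0
    for i, a in enumerate(ends):
        dist, paths = nx.single_source_dijkstra(g, a)
        for b in ends[i + 1 :]:
            if b in dist and dist[b] > best_len:
                best_len = dist[b]
                best = paths[b]
    if best is None or len(best) < 2:
        return None
    ordered = pts[best]  # (row, col)
    return ordered[:, ::-1].astype(float)  # -> (col, row)


def _smooth_resample(path: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    """Spline-smooth an ordered polyline and resample at ~``spacing`` px."""
    if len(path) < 4:
        return path
    # de-duplicate consecutive points for splprep
    keep = np.concatenate([[True], np.linalg.norm(np.diff(path, axis=0), axis=1) > 1e-9])
    path = path[keep]
    if len(path) < 4:
        return path
    tck, _ = splprep(path.T, s=len(path) * 0.5)
    total = np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1))
    n = max(int(total / spacing), 5)
    u = np.linspace(0, 1, n)
    return np.column_stack(splev(u, tck))


def _extend_to_pole(path: np.ndarray, mask: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Extend both centerline ends along their tangents until leaving the mask."""
    h, w = mask.shape

    def inside(p: np.ndarray) -> bool:
        c, r = int(round(p[0])), int(round(p[1]))
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    out = [path]
    for end, ref in ((path[0], path[min(4, len(path) - 1)]), (path[-1], path[max(-5, -len(path))])):
        tangent = end - ref
        norm = np.linalg.norm(tangent)
        if norm < 1e-9:
            continue
        tangent /= norm
        ext = []
        p = end.copy()
        for _ in range(int(w / step)):
            p = p + tangent * step
            if not inside(p):
                break
            ext.append(p.copy())
        if ext:
            if np.allclose(end, path[0]):
                out.insert(0, np.array(ext[::-1]))
            else:
                out.append(np.array(ext))
    return np.vstack(out)


def segment_cells(
    phase: np.ndarray,
    pixel_size: float = PIXEL_SIZE_NM,
    min_area_px: int = 30,
) -> list[CellGeometry]:
    """Segment dark cells in a phase-contrast-like image.

    Cells touching the frame border are excluded.  Centerlines come from
    skeletonizing each mask, pruning to the longest path, smoothing and
    extending to the poles; cell length is the centerline arc length.
    """
    img = np.asarray(phase, float)
    if img.max() == img.min():
        log.warning("blank image: no cells found")
        return []
    mask = img < threshold_otsu(img)
    mask = closing(mask, disk(2))
    mask = binary_fill_holes(mask)
    mask = clear_border(mask)
    labels = label(mask)
    geoms: list[CellGeometry] = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        cell_mask = labels == region.label
        skel = skeletonize(cell_mask)
        path = _longest_skeleton_path(skel)
        if path is None:
            log.warning("region %d: centerline not found; skipped", region.label)
            continue
        path = _smooth_resample(path)
        path = _extend_to_pole(path, cell_mask)
        arclen = np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1))
        edt = distance_transform_edt(cell_mask)
        # width from the EDT along the central half of the centerline
        mid = path[len(path) // 4 : max(len(path) // 4 + 1, 3 * len(path) // 4)]
        ridge = edt[
            np.clip(np.round(mid[:, 1]).astype(int), 0, edt.shape[0] - 1),
            np.clip(np.round(mid[:, 0]).astype(int), 0, edt.shape[1] - 1),
        ]
        contours = find_contours(cell_mask.astype(float), 0.5)
        boundary = max(contours, key=len)[:, ::-1]  # (col, row)
        com = (region.centroid[1], region.centroid[0])  # (col, row)
        geoms.append(
            CellGeometry(
                cell_id=len(geoms),
                boundary=boundary,
                center_of_mass=com,
                centerline=path,
                length_nm=float(arclen * pixel_size),
                width_nm=float(2.0 * ridge.mean() * pixel_size),
                mask=cell_mask,
            )
        )
    if not geoms:
        log.warning("no cells found")
    return geoms


# --------------------------------------------------------------------------
# spot detection and fitting


def detect_spots(
    fluor: np.ndarray,
    geom: CellGeometry,
    threshold_k: float = THRESHOLD_K,
    abs_threshold: float | None = None,
) -> list[tuple[int, int]]:
    """Seed pixels (col, row) of above-threshold clusters inside the cell mask.

    The threshold is either absolute or ``median + k * 1.4826 * MAD`` of the
    in-cell intensities.  Clusters covering more than a quarter of the cell
    area are rejected as artifacts.
    """
    if geom.mask is None:
        raise ValueError("geometry has no pixel mask; segment with mask retention")
    img = np.asarray(fluor, float)
    vals = img[geom.mask]
    if abs_threshold is None:
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        if mad == 0:  # noiseless rendering: fall back to a peak-relative cut
            thr = med + 0.1 * (vals.max() - med)
        else:
            thr = med + threshold_k * 1.4826 * mad
    else:
        thr = abs_threshold
    above = (img > thr) & geom.mask
    labels = label(above)
    max_area = geom.mask.sum() / 4.0
    seeds = []
    for region in regionprops(labels, intensity_image=img):
        if region.area > max_area:
            log.warning("cluster of %d px rejected as artifact", region.area)
            continue
        r, c = region.coords[np.argmax(img[tuple(region.coords.T)])]
        seeds.append((int(c), int(r)))
    return seeds


def _gauss2d(coords, amplitude, col0, row0, sigma, offset):
    c, r = coords
    return (
        amplitude * np.exp(-((c - col0) ** 2 + (r - row0) ** 2) / (2.0 * sigma**2)) + offset
    ).ravel()


def fit_spot_gaussian(
    img: np.ndarray,
    seed: tuple[int, int],
    window_half: int = FIT_WINDOW_HALF,
    sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
    sigma0: float = 1.2,
) -> SpotFit | None:
    """Fit ``A * exp(-|p - c|^2 / (2 sigma^2)) + B`` in a window around ``seed``.

    Returns ``None`` (spot dropped) when the window leaves the frame, the
    fit does not converge, or sigma ends on its bounds.
    """
    img = np.asarray(img, float)
    h, w = img.shape
    c0, r0 = seed
    if not (window_half <= c0 < w - window_half and window_half <= r0 < h - window_half):
        log.warning("seed (%d, %d) too close to the frame edge; dropped", c0, r0)
        return None
    cols = np.arange(c0 - window_half, c0 + window_half + 1)
    rows = np.arange(r0 - window_half, r0 + window_half + 1)
    win = img[np.ix_(rows, cols)]
    cc, rr = np.meshgrid(cols, rows)
    bg0 = float(np.median(win))
    p0 = [max(win.max() - bg0, 1e-3), float(c0), float(r0), sigma0, bg0]
    lo = [0.0, cols[0] - 0.5, rows[0] - 0.5, sigma_bounds[0], -np.inf]
    hi = [np.inf, cols[-1] + 0.5, rows[-1] + 0.5, sigma_bounds[1], np.inf]
    try:
        popt, _ = curve_fit(
            _gauss2d, (cc, rr), win.ravel(), p0=p0, bounds=(lo, hi), maxfev=2000
        )
    except RuntimeError:
        log.warning("Gaussian fit did not converge at seed (%d, %d); dropped", c0, r0)
        return None
    amplitude, col, row, sigma, offset = popt
    eps = 1e-6
    if sigma <= sigma_bounds[0] + eps or sigma >= sigma_bounds[1] - eps:
        log.warning("fitted sigma %.2f px on bounds at seed (%d, %d); dropped", sigma, c0, r0)
        return None
    residual = float(np.linalg.norm(win.ravel() - _gauss2d((cc, rr), *popt)))
    return SpotFit(
        channel="",
        frame=-1,
        col=float(col),
        row=float(row),
        amplitude=float(amplitude),
        sigma=float(sigma),
        offset=float(offset),
        residual=residual,
    )


# --------------------------------------------------------------------------
# cell-frame transform


def _project_on_polyline(p: np.ndarray, poly: np.ndarray, arclen: np.ndarray):
    """Arc length, signed perpendicular distance and clamp flag of a point."""
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len2 = np.sum(ab**2, axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-12, seg_len2)
    t = np.clip(np.sum((p - a) * ab, axis=1) / seg_len2, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d2 = np.sum((p - foot) ** 2, axis=1)
    k = int(np.argmin(d2))
    tangent = ab[k] / np.sqrt(seg_len2[k])
    diff = p - foot[k]
    # positive x = to the left of the tangent direction (screen-up for a
    # left-to-right centerline in image coordinates)
    signed = float(tangent[1] * diff[0] - tangent[0] * diff[1])
    s = float(arclen[k] + t[k] * np.sqrt(seg_len2[k]))
    clamped = (k == 0 and t[0] == 0.0) or (k == len(ab) - 1 and t[-1] == 1.0)
    return s, signed, clamped


def to_cell_frame(
    spot: SpotFit, geom: CellGeometry, pixel_size: float = PIXEL_SIZE_NM
) -> CellFramePosition:
    """Cell-frame (x transversal, y longitudinal) nm coordinates of a fit.

    Sign conventions follow the centerline orientation stored in ``geom``;
    freeze pole identity across a movie with :meth:`CellGeometry.oriented_like`.
    A foot point beyond a centerline end is clamped to that end and flagged.
    """
    p = np.array([spot.col, spot.row], float)
    s, signed, clamped = _project_on_polyline(p, geom.centerline, geom._arclen)
    if clamped:
        log.warning("spot projects beyond the centerline end; clamped")
    return CellFramePosition(
        x_nm=signed * pixel_size,
        y_nm=(s - geom._com_s) * pixel_size,
        clamped=clamped,
    )


# --------------------------------------------------------------------------
# stack-level driver


def _match_geometry(
    geom: CellGeometry, references: list[CellGeometry], tol_px: float
) -> CellGeometry | None:
    """Identify a re-fitted geometry with a first-frame cell by COM proximity."""
    coms = np.array([g.center_of_mass for g in references])
    d = np.linalg.norm(coms - np.asarray(geom.center_of_mass), axis=1)
    k = int(np.argmin(d))
    return references[k] if d[k] <= tol_px else None


def localize_stack(
    stacks: dict[str, np.ndarray],
    pixel_size: float = PIXEL_SIZE_NM,
    threshold_k: float = THRESHOLD_K,
    dt: float = 1.0,
    refit_geometry: bool = True,
    max_spots: int = MAX_SPOTS_PER_CHANNEL,
) -> pd.DataFrame:
    """Localize both fluorescence channels of a rendered/acquired stack.

    Cell geometry is re-fitted each frame (optional) but cell identity and
    pole orientation are frozen at the first frame.  Frames in which a cell
    shows more than ``max_spots`` fits in one channel are dropped for that
    cell and logged.
    """
    phase = stacks["phase"]
    n_frames = phase.shape[0]
    ref_geoms = segment_cells(phase[0], pixel_size)
    if not ref_geoms:
        return pd.DataFrame(columns=DETECTION_COLUMNS)
    tol_px = np.median([g.width_nm for g in ref_geoms]) / pixel_size

    rows = []
    for frame in range(n_frames):
        if refit_geometry and frame > 0:
            geoms = []
            for g in segment_cells(phase[frame], pixel_size):
                ref = _match_geometry(g, ref_geoms, tol_px)
                if ref is None:
                    continue
                g = g.oriented_like(ref)
                g.cell_id = ref.cell_id
                geoms.append(g)
        else:
            geoms = ref_geoms
        for geom in geoms:
            for channel in ("green", "red"):
                if channel not in stacks:
                    continue
                img = stacks[channel][frame]
                fits = []
                for seed in detect_spots(img, geom, threshold_k):
                    fit = fit_spot_gaussian(img, seed)
                    if fit is None:
                        continue
                    fit.channel = channel
                    fit.frame = frame
                    fit.cell_id = geom.cell_id
                    fits.append(fit)
                if len(fits) > max_spots:
                    log.warning(
                        "cell %d frame %d: %d %s spots (> %d); cell dropped this frame",
                        geom.cell_id, frame, len(fits), channel, max_spots,
                    )
                    continue
                for fit in fits:
                    pos = to_cell_frame(fit, geom, pixel_size)
                    rows.append(
                        (
                            geom.cell_id,
                            channel,
                            frame,
                            fit.col,
                            fit.row,
                            pos.x_nm,
                            pos.y_nm,
                            fit.amplitude,
                            fit.sigma,
                            fit.offset,
                            fit.residual,
                        )
                    )
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df["time_s"] = df["frame"] * dt
    return df
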