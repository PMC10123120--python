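"""Link per-frame detections into trajectories; element-to-target distances.

With at most two loci per channel per cell, greedy nearest-neighbour
assignment with a displacement gate and short gap closing is sufficient;
an optimal (Hungarian) assignment is available behind a flag for
validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from locusdyn.trajectory import Trajectory

log = logging.getLogger(__name__)

__all__ = ["DistanceSeries", "link", "nearest_attb_distance", "distances_frame"]

#: maximum per-step displacement accepted by the linker, nm (at ~4 s framing)
MAX_DISP_NM = 800.0
#: maximum number of missed frames closed as a gap
MAX_GAP = 2
#: minimum trajectory length kept, frames
MIN_LEN = 20


@dataclass
class DistanceSeries:
    """Euclidean distance from the element to the nearest attB locus, per frame."""

    cell_id: int
    frames: np.ndarray
    times: np.ndarray  # s
    d_nm: np.ndarray

    def __len__(self) -> int:
        return len(self.frames)


class _OpenTrack:
    __slots__ = ("frames", "times", "xy", "locus_id")

    def __init__(self, locus_id: int):
        self.frames: list[int] = []
        self.times: list[float] = []
        self.xy: list[np.ndarray] = []
        self.locus_id = locus_id


def _assign_greedy(costs: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    """Greedy smallest-cost pairing; ties break on (cost, row, col) order."""
    pairs = []
    used_r: set[int] = set()
    used_c: set[int] = set()
    order = sorted(
        ((costs[i, j], i, j) for i in range(costs.shape[0]) for j in range(costs.shape[1])),
    )
    for cost, i, j in order:
        if cost > max_cost:
            break
        if i in used_r or j in used_c:
            continue
        pairs.append((i, j))
        used_r.add(i)
        used_c.add(j)
    return pairs


def _assign_hungarian(costs: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    big = max_cost * 1e3
    padded = np.where(costs > max_cost, big, costs)
    rows, cols = linear_sum_assignment(padded)
    return [(i, j) for i, j in zip(rows, cols) if costs[i, j] <= max_cost]


def link(
    detections: pd.DataFrame,
    max_disp: float = MAX_DISP_NM,
    max_gap: int = MAX_GAP,
    min_len: int = MIN_LEN,
    method: str = "greedy",
    dt: float | None = None,
) -> list[Trajectory]:
    """Link detections (localize schema) into per-locus trajectories.

    Performed independently per cell and channel.  A detection is appended
    to the open track whose last position is nearest, provided the
    displacement is below ``max_disp``; tracks survive up to ``max_gap``
    missed frames.  Unmatched detections open new tracks.  Tracks shorter
    than ``min_len`` are discarded.
    """
    assigner = {"greedy": _assign_greedy, "hungarian": _assign_hungarian}[method]
    if "time_s" not in detections.columns:
        detections = detections.assign(time_s=detections["frame"] * (dt or 1.0))
    trajectories: list[Trajectory] = []
    for (cell_id, channel), group in detections.groupby(["cell_id", "channel"], sort=True):
        # deterministic input order regardless of how the CSV was produced
        group = group.sort_values(["frame", "x_nm", "y_nm"], kind="mergesort")
        open_tracks: list[_OpenTrack] = []
        closed: list[_OpenTrack] = []
        next_id = 0
        for frame, g in group.groupby("frame", sort=True):
            frame = int(frame)
            xy = g[["x_nm", "y_nm"]].to_numpy(float)
            times = g["time_s"].to_numpy(float)
            # retire tracks whose gap is already too long
            still = []
            for tr in open_tracks:
                (closed if frame - tr.frames[-1] > max_gap + 1 else still).append(tr)
            open_tracks = still
            pairs: list[tuple[int, int]] = []
            if open_tracks and len(xy):
                last = np.array([tr.xy[-1] for tr in open_tracks])
                costs = np.linalg.norm(last[:, None, :] - xy[None, :, :], axis=2)
                pairs = assigner(costs, max_disp)
            matched = set()
            for i, j in pairs:
                tr = open_tracks[i]
                tr.frames.append(frame)
                tr.times.append(times[j])
                tr.xy.append(xy[j])
                matched.add(j)
            for j in range(len(xy)):
                if j in matched:
                    continue
                tr = _OpenTrack(next_id)
                next_id += 1
                tr.frames.append(frame)
                tr.times.append(times[j])
                tr.xy.append(xy[j])
                open_tracks.append(tr)
        closed.extend(open_tracks)
        for tr in sorted(closed, key=lambda t: t.locus_id):
            if len(tr.frames) < min_len:
                continue
            step = dt
            if step is None:
                diffs = np.diff(tr.times)
                step = float(np.median(diffs)) if len(diffs) else 1.0
            trajectories.append(
                Trajectory(
                    cell_id=int(cell_id),
                    locus_id=tr.locus_id,
                    channel=str(channel),
                    frames=np.array(tr.frames),
                    times=np.array(tr.times),
                    xy=np.array(tr.xy),
                    dt=step,
                )
            )
    return trajectories


def nearest_attb_distance(ice: Trajectory, attbs: list[Trajectory]) -> DistanceSeries:
    """Per-frame distance from the element to the nearest attB locus.

    Defined only on frames where the element and at least one attB locus
    were both detected.
    """
    attbs = [a for a in attbs if a.cell_id == ice.cell_id]
    if not attbs:
        raise ValueError("no attB trajectory shares the element's cell id")
    frames, times, dists = [], [], []
    lookup = [dict(zip(a.frames.tolist(), a.xy)) for a in attbs]
    for k, frame in enumerate(ice.frames.tolist()):
        candidates = [table[frame] for table in lookup if frame in table]
        if not candidates:
            continue
        d = min(float(np.linalg.norm(ice.xy[k] - c)) for c in candidates)
        frames.append(frame)
        times.append(ice.times[k])
        dists.append(d)
    if not frames:
        log.warning("cell %d: element and attB share no frames", ice.cell_id)
    return DistanceSeries(
        cell_id=ice.cell_id,
        frames=np.array(frames, int),
        times=np.array(times, float),
        d_nm=np.array(dists, float),
    )


def distances_frame(series: list[DistanceSeries]) -> pd.DataFrame:
    """Flatten distance series into the `cell_id,frame,time_s,d_nm` schema."""
    rows = [
        pd.DataFrame(
            {"cell_id": s.cell_id, "frame": s.frames, "time_s": s.times, "d_nm": s.d_nm}
        )
        for s in series
        if len(s)
    ]
    if not rows:
        return pd.DataFrame(columns=["cell_id", "frame", "time_s", "d_nm"])
    return pd.concat(rows, ignore_index=True)
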