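"""Trajectory container shared by the simulators, the tracker and the analyses.

Positions are in cell-frame coordinates: ``x`` is the signed transversal
distance to the cell centerline, ``y`` the signed longitudinal arc-length
position relative to the projection of the cell's center of mass — both in
nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the trajectories CSV
TRAJECTORY_COLUMNS = ["cell_id", "locus_id", "channel", "frame", "time_s", "x_nm", "y_nm"]


@dataclass(eq=False)  # identity semantics: array fields make value-eq ill-defined
class Trajectory:
    """Time-stamped cell-frame positions of one labelled locus."""

    cell_id: int
    locus_id: int
    channel: str
    frames: np.ndarray  # int, strictly increasing
    times: np.ndarray  # s
    xy: np.ndarray  # (n, 2) nm, columns (x, y)
    dt: float  # nominal frame interval, s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.frames) != len(self.xy) or len(self.times) != len(self.xy):
            raise ValueError("frames, times and xy must have equal length")
        if len(self.frames) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def on_regular_grid(self) -> np.ndarray:
        """Positions on the full frame grid with NaN at gap frames, shape (n_grid, 2)."""
        lo, hi = self.frames[0], self.frames[-1]
        grid = np.full((hi - lo + 1, 2), np.nan)
        grid[self.frames - lo] = self.xy
        return grid

    def steps(self) -> np.ndarray:
        """Frame-to-frame displacement magnitudes (nm) between consecutive frames.

        Displacements across gaps are excluded.
        """
        if len(self) < 2:
            return np.empty(0)
        consecutive = np.diff(self.frames) == 1
        d = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        return d[consecutive]

    def radius_of_gyration(self) -> float:
        """RMS distance (nm) of the positions from their own mean."""
        centred = self.xy - self.xy.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into the tidy CSV schema."""
    rows = []
    for t in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "locus_id": t.locus_id,
                    "channel": t.channel,
                    "frame": t.frames,
                    "time_s": t.times,
                    "x_nm": t.xy[:, 0],
                    "y_nm": t.xy[:, 1],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(rows, ignore_index=True)[TRAJECTORY_COLUMNS]


def trajectories_from_frame(df: pd.DataFrame, dt: float | None = None) -> list[Trajectory]:
    """Rebuild :class:`Trajectory` objects from the tidy CSV schema."""
    trajs = []
    for (cell_id, locus_id, channel), g in df.groupby(
        ["cell_id", "locus_id", "channel"], sort=True
    ):
        g = g.sort_values("frame")
        times = g["time_s"].to_numpy(float)
        if dt is None:
            step = np.median(np.diff(times)) if len(times) > 1 else 1.0
        else:
            step = dt
        trajs.append(
            Trajectory(
                cell_id=int(cell_id),
                locus_id=int(locus_id),
                channel=str(channel),
                frames=g["frame"].to_numpy(int),
                times=times,
                xy=g[["x_nm", "y_nm"]].to_numpy(float),
                dt=float(step),
            )
        )
    return trajs
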