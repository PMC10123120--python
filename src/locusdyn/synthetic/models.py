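"""Trajectory simulators for the three candidate subdiffusion mechanisms.

* ``fbm`` — fractional Brownian motion: independent exact fGn series per
  axis, each with its own (alpha, D).  Ergodic, antipersistent increments.
* ``ctrw`` — continuous-time random walk: Gaussian jumps separated by
  Pareto waiting times with tail exponent beta in (0, 1), sampled on the
  regular frame grid.  Subdiffusive in the ensemble sense but ageing and
  non-ergodic: its time-averaged MSD grows nearly linearly while the
  ensemble-averaged MSD grows as tau**beta.
* ``od`` — obstructed diffusion: nearest-neighbour lattice walk among fixed
  randomly placed reflecting obstacles.  Subdiffusive below the percolation
  threshold yet with uncorrelated steps, hence no antipersistent velocity
  autocorrelation.

These are the models the anomalous-diffusion diagnostics are designed to
tell apart.
"""

from __future__ import annotations

import numpy as np

from locusdyn._rng import as_generator, substream
from locusdyn.config import SimConfig
from locusdyn.synthetic.fgn import simulate_fbm_path
from locusdyn.trajectory import Trajectory

__all__ = ["simulate_trajectory", "simulate_ensemble"]

#: obstructed-diffusion lattice constant, nm (far below the cell width)
OD_LATTICE_NM = 20.0
#: lattice moves attempted per frame interval
OD_MOVES_PER_FRAME = 25
#: CTRW waiting-time scale, s
CTRW_T0_S = 1.0

_OD_DIRS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])


def _fbm_xy(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    x = simulate_fbm_path(cfg.alpha_x, cfg.D_x, cfg.dt, cfg.n_frames, rng)
    y = simulate_fbm_path(cfg.alpha_y, cfg.D_y, cfg.dt, cfg.n_frames, rng)
    return np.column_stack([x, y])


def _ctrw_xy(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    total_time = (cfg.n_frames - 1) * cfg.dt
    # Pareto waiting times w = t0 * U**(-1/beta); heavy tail, infinite mean
    waits = []
    elapsed = 0.0
    while elapsed <= total_time:
        block = CTRW_T0_S * rng.uniform(size=256) ** (-1.0 / cfg.ctrw_beta)
        waits.append(block)
        elapsed += block.sum()
    event_times = np.cumsum(np.concatenate(waits))
    event_times = event_times[event_times <= total_time]
    n_jumps = len(event_times)
    # Gaussian jumps matched to the FBM per-frame step scale on each axis
    sx = np.sqrt(cfg.D_x * cfg.dt**cfg.alpha_x)
    sy = np.sqrt(cfg.D_y * cfg.dt**cfg.alpha_y)
    jumps = rng.standard_normal((n_jumps, 2)) * np.array([sx, sy])
    cum = np.vstack([np.zeros(2), np.cumsum(jumps, axis=0)])
    grid = np.arange(cfg.n_frames) * cfg.dt
    idx = np.searchsorted(event_times, grid, side="right")
    return cum[idx]


def _od_xy(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_moves = (cfg.n_frames - 1) * OD_MOVES_PER_FRAME
    size = 401  # periodic lattice, +-4 um span: walkers never wrap at these times
    obstacles = rng.uniform(size=(size, size)) < cfg.od_obstacle_density
    pos = np.array([size // 2, size // 2])
    obstacles[pos[0], pos[1]] = False
    path = np.empty((cfg.n_frames, 2), dtype=int)
    path[0] = pos
    dirs = _OD_DIRS[rng.integers(0, 4, size=n_moves)]
    k = 0
    for frame in range(1, cfg.n_frames):
        for _ in range(OD_MOVES_PER_FRAME):
            trial = (pos + dirs[k]) % size
            k += 1
            if not obstacles[trial[0], trial[1]]:
                pos = trial
        path[frame] = pos
    return (path - path[0]) * OD_LATTICE_NM


_MODEL_FNS = {"fbm": _fbm_xy, "ctrw": _ctrw_xy, "od": _od_xy}


def simulate_trajectory(
    cfg: SimConfig,
    rng: int | np.random.Generator | None = None,
    cell_id: int = 0,
    locus_id: int = 0,
    channel: str = "green",
) -> Trajectory:
    """Simulate one trajectory under ``cfg.model`` starting at the origin."""
    try:
        fn = _MODEL_FNS[cfg.model]
    except KeyError:
        raise ValueError(f"unknown model {cfg.model!r}") from None
    rng = as_generator(cfg.seed if rng is None else rng)
    xy = fn(cfg, rng)
    frames = np.arange(cfg.n_frames)
    return Trajectory(
        cell_id=cell_id,
        locus_id=locus_id,
        channel=channel,
        frames=frames,
        times=frames * cfg.dt,
        xy=xy,
        dt=cfg.dt,
    )


def simulate_ensemble(cfg: SimConfig) -> list[Trajectory]:
    """Simulate ``cfg.n_traj`` independent trajectories from split substreams."""
    return [
        simulate_trajectory(cfg, rng=substream(cfg.seed, "simulate", i), cell_id=i)
        for i in range(cfg.n_traj)
    ]
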