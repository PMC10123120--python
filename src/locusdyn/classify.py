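"""Behaviour classification of element trajectories and position statistics.

An element (ICE) trajectory in a transconjugant is assigned exactly one of
four labels by a deterministic decision cascade:

1. ``integrated``   — the median distance to the nearest attB locus over the
   final half of the distance series stays below the integration threshold
   (300 nm by default, giving margin over the ~200 nm tether of a truly
   integrated pair) and that stretch contains no distance jump above 500 nm;
2. ``mobile_fast``  — otherwise, if any frame-to-frame step exceeds 200 nm
   and the longitudinal span covers more than 40% of the cell length
   (operationalizing "fast motion spanning a large portion of the cell");
3. ``mobile_local`` — otherwise, if any step exceeds 200 nm;
4. ``trapped``      — otherwise.

The same module pools normalized longitudinal positions
``(y + L/2) / L in [0, 1]`` into the distribution whose peaks locate attB
near 1/4 and 3/4 of the cell axis and freely moving elements near mid-cell.
All thresholds are explicit, configurable stand-ins for the qualitative
descriptions they implement and are echoed in every output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal

from locusdyn.track import DistanceSeries
from locusdyn.trajectory import Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierThresholds",
    "BehaviorLabel",
    "PositionDistribution",
    "classify_ice",
    "classify_population",
    "class_fractions",
    "mobility_filter",
    "position_distribution",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Explicit operational thresholds of the behaviour cascade."""

    integration_distance_nm: float = 300.0
    integration_jump_nm: float = 500.0
    mobility_step_nm: float = 200.0
    span_fraction: float = 0.40


@dataclass
class BehaviorLabel:
    """Label plus the per-cell evidence that produced it."""

    cell_id: int
    label: str
    median_d_nm: float  # over the final half of the distance series (NaN if absent)
    max_step_nm: float
    span_frac: float  # longitudinal span / cell length
    rg_nm: float  # radius of gyration
    restricted: bool = False  # no distance series: integration could not be tested


@dataclass
class PositionDistribution:
    """Histogram of normalized longitudinal positions in [0, 1]."""

    edges: np.ndarray
    counts: np.ndarray
    n: int
    n_dropped: int
    folded: bool
    peaks: np.ndarray  # bin-center locations of local maxima, descending height
    tag: str = ""


def classify_ice(
    ice: Trajectory,
    distances: DistanceSeries | None,
    cell_length_nm: float,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> BehaviorLabel:
    """Classify one element trajectory by the decision cascade."""
    steps = ice.steps()
    max_step = float(steps.max()) if len(steps) else 0.0
    span = float(ice.y.max() - ice.y.min())
    span_frac = span / cell_length_nm if cell_length_nm > 0 else np.nan
    rg = ice.radius_of_gyration()

    median_d = np.nan
    restricted = distances is None or len(distances) == 0
    if not restricted:
        half = distances.d_nm[len(distances) // 2 :]
        median_d = float(np.median(half))
        jumps = np.abs(np.diff(half))
        no_big_jump = not np.any(jumps > thresholds.integration_jump_nm)
        if median_d < thresholds.integration_distance_nm and no_big_jump:
            return BehaviorLabel(ice.cell_id, "integrated", median_d, max_step, span_frac, rg)
    else:
        log.warning(
            "cell %d: no distance series; integration cannot be tested", ice.cell_id
        )

    if max_step > thresholds.mobility_step_nm and span_frac > thresholds.span_fraction:
        label = "mobile_fast"
    elif max_step > thresholds.mobility_step_nm:
        label = "mobile_local"
    else:
        label = "trapped"
    return BehaviorLabel(ice.cell_id, label, median_d, max_step, span_frac, rg, restricted)


def classify_population(
    ices: list[Trajectory],
    distances: dict[int, DistanceSeries],
    cell_lengths: pd.Series,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Classify every element trajectory; one row per cell.

    ``distances`` maps cell id to its nearest-attB distance series and
    ``cell_lengths`` cell id to length (nm).
    """
    rows = [
        asdict(
            classify_ice(
                ice,
                distances.get(ice.cell_id),
                float(cell_lengths.get(ice.cell_id, np.nan)),
                thresholds,
            )
        )
        for ice in ices
    ]
    return pd.DataFrame(rows).sort_values("cell_id", ignore_index=True)


def class_fractions(labels: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Per-class fractions with binomial standard errors (fraction scale)."""
    s = labels["label"] if isinstance(labels, pd.DataFrame) else labels
    n = len(s)
    out = []
    for label, count in s.value_counts().sort_index().items():
        p = count / n
        out.append(
            {
                "label": label,
                "count": int(count),
                "n": n,
                "fraction": p,
                "se": float(np.sqrt(p * (1 - p) / n)),
            }
        )
    return pd.DataFrame(out)


def mobility_filter(trajs: list[Trajectory], min_step_nm: float = 200.0) -> list[Trajectory]:
    """Keep trajectories with at least one frame-to-frame step above threshold.

    This is the inclusion rule used before pooling element positions, which
    removes elements that have already integrated.
    """
    kept = []
    for t in trajs:
        steps = t.steps()
        if len(steps) and steps.max() > min_step_nm:
            kept.append(t)
    return kept


def position_distribution(
    trajs: list[Trajectory],
    cell_lengths: pd.Series,
    n_bins: int = 25,
    fold: bool = False,
    tolerance_nm: float = 200.0,
    tag: str = "",
) -> PositionDistribution:
    """Pooled histogram of normalized longitudinal positions over all frames.

    Each position contributes ``(y + L/2) / L``; values outside
    ``[-tol, L + tol]`` (scaled) are dropped and counted.  ``fold=True``
    averages each position with its pole mirror ``1 - f``, removing the
    arbitrary pole orientation.
    """
    fracs = []
    dropped = 0
    for t in trajs:
        L = float(cell_lengths.get(t.cell_id, np.nan))
        if not np.isfinite(L) or L <= 0:
            dropped += len(t)
            continue
        f = (t.y + L / 2.0) / L
        tol = tolerance_nm / L
        ok = (f >= -tol) & (f <= 1.0 + tol)
        dropped += int((~ok).sum())
        fracs.append(np.clip(f[ok], 0.0, 1.0))
    values = np.concatenate(fracs) if fracs else np.empty(0)
    if fold and len(values):
        values = np.concatenate([values, 1.0 - values])
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx, _ = signal.find_peaks(
        np.concatenate([[-np.inf], counts, [-np.inf]]),
        prominence=0.05 * max(counts.max(), 1),
    )
    idx = idx - 1
    peaks = centers[idx[np.argsort(counts[idx])[::-1]]] if len(idx) else np.empty(0)
    return PositionDistribution(
        edges=edges,
        counts=counts,
        n=int(counts.sum()),
        n_dropped=dropped,
        folded=fold,
        peaks=peaks,
        tag=tag,
    )
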