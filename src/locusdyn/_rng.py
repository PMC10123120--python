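"""Splittable random-number streams.

One user-facing integer seed is expanded into independent per-cell /
per-trajectory / per-stage streams through :class:`numpy.random.SeedSequence`
spawn keys, so results are reproducible regardless of execution order.
"""

from __future__ import annotations

import numpy as np

# stable small integers for named stages; values are arbitrary but frozen
_STAGE_KEYS = {
    "simulate": 1,
    "render": 2,
    "localize": 3,
    "track": 4,
    "dynamics": 5,
    "classify": 6,
    "noise": 7,
}


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a generator for stream ``(seed, *keys)``.

    String keys name pipeline stages; integer keys index cells, loci or
    trajectories.  Identical ``(seed, keys)`` always yields the identical
    stream.
    """
    spawn_key = tuple(_STAGE_KEYS[k] if isinstance(k, str) else int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))


def as_generator(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, ``None`` or an existing generator to a generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
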