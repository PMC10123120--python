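"""Exact fractional Gaussian noise (fGn) along one axis.

A locus performing fractional Brownian motion with per-axis mean square
displacement ``MSD(tau) = D * tau**alpha`` has stationary Gaussian frame
increments with autocovariance

    gamma(k) = (D * dt**alpha / 2) * (|k+1|**alpha - 2|k|**alpha + |k-1|**alpha)

For ``alpha < 1`` successive increments are anti-correlated (antipersistent),
the signature of motion in a viscoelastic medium; ``alpha = 1`` recovers
ordinary Brownian motion with independent increments.

The default sampler uses circulant embedding (Davies-Harte): the Toeplitz
increment covariance is embedded in a circulant matrix diagonalized by the
FFT, giving exact draws in O(n log n).  The embedding is non-negative
definite for all alpha in (0, 1]; a dense Cholesky sampler is provided both
as a fallback and as an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, toeplitz

from locusdyn._rng import as_generator

__all__ = [
    "fgn_autocovariance",
    "simulate_fgn_axis",
    "simulate_fgn_cholesky",
    "simulate_fbm_path",
]


def fgn_autocovariance(k, alpha: float, D: float = 1.0, dt: float = 1.0) -> np.ndarray:
    """Autocovariance gamma(k) of fGn increments at integer lag(s) ``k``."""
    k = np.abs(np.asarray(k, dtype=float))
    scale = 0.5 * D * dt**alpha
    return scale * ((k + 1.0) ** alpha - 2.0 * k**alpha + np.abs(k - 1.0) ** alpha)


def _check_params(alpha: float, n_frames: int) -> None:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    if n_frames < 2:
        raise ValueError("n_frames must be at least 2")


def simulate_fgn_axis(
    alpha: float,
    D: float,
    dt: float,
    n_frames: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Draw ``n_frames - 1`` exact fGn increments (nm) by circulant embedding.

    The cumulative sum (with a zero prepended) is an FBM path whose ensemble
    MSD at lag ``k*dt`` equals ``D * (k*dt)**alpha`` exactly in expectation.
    """
    _check_params(alpha, n_frames)
    rng = as_generator(seed)
    n = n_frames - 1
    if alpha == 1.0:
        # Brownian limit: i.i.d. increments
        return rng.standard_normal(n) * np.sqrt(D * dt)

    # circulant first row of size 2n: gamma(0..n), then mirrored gamma(n-1..1)
    g = fgn_autocovariance(np.arange(n + 1), alpha, D, dt)
    c = np.concatenate([g, g[-2:0:-1]])
    m = len(c)  # 2n
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        raise FloatingPointError(
            f"circulant embedding not non-negative definite (min eigenvalue {lam.min():g})"
        )
    lam = np.clip(lam, 0.0, None)

    # exact Davies-Harte draw: Hermitian-symmetric spectral noise
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    half = m // 2
    w[half] = np.sqrt(lam[half] / m) * rng.standard_normal()
    u = rng.standard_normal(half - 1)
    v = rng.standard_normal(half - 1)
    mid = np.sqrt(lam[1:half] / (2.0 * m)) * (u + 1j * v)
    w[1:half] = mid
    w[half + 1 :] = np.conj(mid[::-1])
    return np.fft.fft(w).real[:n]


def simulate_fgn_cholesky(
    alpha: float,
    D: float,
    dt: float,
    n_frames: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Dense O(n^3) fGn sampler via Cholesky of the Toeplitz covariance.

    Exact like the circulant route but independent of it; used as fallback
    and as the cross-check oracle in the test suite.
    """
    _check_params(alpha, n_frames)
    rng = as_generator(seed)
    n = n_frames - 1
    g = fgn_autocovariance(np.arange(n), alpha, D, dt)
    L = cholesky(toeplitz(g), lower=True)
    return L @ rng.standard_normal(n)


def simulate_fbm_path(
    alpha: float,
    D: float,
    dt: float,
    n_frames: int,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """FBM positions (nm) of length ``n_frames`` starting at 0."""
    inc = simulate_fgn_axis(alpha, D, dt, n_frames, seed)
    out = np.empty(n_frames)
    out[0] = 0.0
    np.cumsum(inc, out=out[1:])
    return out
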