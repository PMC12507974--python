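"""Exact fractional Gaussian noise / fractional Brownian motion synthesis.

Fractional Gaussian noise (fGn) with Hurst exponent H in (0, 1) is the
stationary increment process of fractional Brownian motion (fBm); its
autocovariance at lag k is

    gamma(k) = 0.5 * (|k+1|**2H - 2|k|**2H + |k-1|**2H)

Sampling uses circulant embedding (Davies–Harte): the covariance sequence
is embedded in a circulant matrix diagonalised by the FFT, giving an
exact draw in O(n log n).  If the embedding of size 2(n-1) is not
non-negative definite the size is doubled a few times; as a last resort
the O(n^2) Hosking recursion (also exact) is used.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["fgn_autocovariance", "gen_fgn", "gen_fbm"]


def fgn_autocovariance(n_lags: int, hurst: float) -> np.ndarray:
    """fGn autocovariance gamma(0..n_lags-1) for unit-variance increments."""
    k = np.arange(n_lags, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (
        np.abs(k + 1) ** h2 - 2.0 * np.abs(k) ** h2 + np.abs(k - 1) ** h2
    )


def _gen_fgn_hosking(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact O(n^2) Durbin–Levinson sampler; fallback for failed embeddings."""
    gamma = fgn_autocovariance(n, hurst)
    out = np.empty(n)
    out[0] = rng.standard_normal() * np.sqrt(gamma[0])
    phi = np.zeros(n)
    v = gamma[0]
    for t in range(1, n):
        phi_t = (gamma[t] - phi[:t - 1] @ gamma[1:t][::-1]) / v if t > 1 else gamma[1] / v
        phi[:t - 1] = phi[:t - 1] - phi_t * phi[:t - 1][::-1]
        phi[t - 1] = phi_t
        v *= 1.0 - phi_t**2
        out[t] = phi[:t] @ out[:t][::-1] + rng.standard_normal() * np.sqrt(v)
    return out


def gen_fgn(
    n: int, hurst: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` samples of exact unit-variance fGn with the given Hurst.

    Reproducible per seed.  H = 0.5 reduces to white Gaussian noise.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # circulant embedding; double the size if eigenvalues dip negative
    m = 2 * (n - 1)
    for _ in range(4):
        half = m // 2
        gamma = fgn_autocovariance(half + 1, hurst)
        row = np.concatenate([gamma, gamma[-2:0:-1]])  # length m
        eig = np.fft.rfft(row).real
        if eig.min() > -1e-8 * eig.max():
            eig = np.clip(eig, 0.0, None)
            # complex Gaussian weights -> two independent real draws; use one
            z = rng.standard_normal(half + 1) + 1j * rng.standard_normal(half + 1)
            z[0] = z[0].real * np.sqrt(2.0)
            z[-1] = z[-1].real * np.sqrt(2.0)
            w = z * np.sqrt(eig / (2.0 * m))
            sample = np.fft.irfft(w, n=m) * m
            return sample[:n]
        m *= 2
    warnings.warn(
        f"circulant embedding not non-negative definite for H={hurst}, n={n}; "
        "falling back to Hosking recursion",
        RuntimeWarning,
        stacklevel=2,
    )
    return _gen_fgn_hosking(n, hurst, rng)


def gen_fbm(
    n: int, hurst: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Fractional Brownian motion path: cumulative sum of exact fGn.

    The path starts at its first increment (no prepended zero), so the
    returned array has length ``n``.
    """
    return np.cumsum(gen_fgn(n, hurst, seed))
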