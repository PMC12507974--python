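"""Detrended fluctuation analysis (DFA).

DFA quantifies the temporal structure of a time series through a scaling
exponent alpha.  The series is mean-centred and integrated into a
profile; the profile is cut into non-overlapping windows of size n, a
least-squares polynomial is removed within each window, and the RMS
residual F(n) is recorded.  For scale-free series F(n) ~ n**alpha, and
alpha is read off as the least-squares slope of log F(n) against log n.

Interpretation anchors: alpha = 0.5 for white noise, 1.5 for Brownian
motion; fractional Gaussian noise with Hurst exponent H gives alpha = H
and fractional Brownian motion gives alpha = H + 1.  For standing
posture, radial sway typically scales in 1 < alpha < 1.5 — an
antipersistent, tightly regulated regime.

Defaults are DFA-1 (linear detrending) over 20 log-spaced window sizes
from 16 samples to a quarter of the series length, windows anchored at
the series start with any short tail discarded.  Fluctuations are not
additionally evaluated on the reversed series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DFAConfig", "DFAResult", "EstimationError", "profile", "fluctuation", "estimate_alpha"]


class EstimationError(RuntimeError):
    """Raised when too few valid points remain for the log-log fit."""


@dataclass(frozen=True)
class DFAConfig:
    """Window layout and detrending order for DFA.

    ``max_window`` below 1 is read as a fraction of the series length
    (default 0.25 → N/4); values >= 1 are absolute sample counts.
    """

    min_window: int = 16
    max_window: float = 0.25
    n_windows: int = 20
    detrend_order: int = 1

    def __post_init__(self) -> None:
        if self.min_window < self.detrend_order + 2:
            raise ValueError("min_window must be at least detrend_order + 2")
        if self.n_windows < 4:
            raise ValueError("need at least 4 window sizes")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be non-negative")

    def window_sizes(self, n_samples: int) -> np.ndarray:
        """Strictly increasing integer window sizes, log-spaced."""
        max_w = (
            int(self.max_window * n_samples)
            if self.max_window < 1
            else int(self.max_window)
        )
        if max_w <= self.min_window:
            raise ValueError(
                f"series of {n_samples} samples too short for windows "
                f"[{self.min_window}, {max_w}]"
            )
        sizes = np.unique(
            np.rint(
                np.logspace(
                    np.log10(self.min_window), np.log10(max_w), self.n_windows
                )
            ).astype(int)
        )
        return sizes


@dataclass(frozen=True)
class DFAResult:
    """Fitted scaling exponent with its log-log regression points."""

    alpha: float
    points: tuple[tuple[float, float], ...]  # (log10 n, log10 F(n))
    fit_r2: float
    dropped: tuple[int, ...] = field(default_factory=tuple)  # window sizes with F=0


def profile(series: np.ndarray) -> np.ndarray:
    """Integrated, mean-centred series (the DFA 'profile')."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1-D with at least 2 samples")
    return np.cumsum(series - series.mean())


def fluctuation(prof: np.ndarray, n: int, detrend_order: int = 1) -> float:
    """RMS detrended fluctuation F(n) at window size ``n``.

    The profile is cut into floor(N/n) non-overlapping windows from the
    start (discarding any short tail); a degree-``detrend_order``
    polynomial is removed from each window by least squares and the RMS of
    all residuals across the used windows is returned.
    """
    prof = np.asarray(prof, dtype=float)
    if n < detrend_order + 2:
        raise ValueError(f"window size {n} too small for degree {detrend_order}")
    if n > prof.size:
        raise ValueError(f"window size {n} exceeds profile length {prof.size}")
    n_win = prof.size // n
    seg = prof[: n_win * n].reshape(n_win, n)
    # shared design matrix -> batched residuals via an orthonormal basis
    t = np.arange(n, dtype=float)
    design = np.vander(t, detrend_order + 1)
    q, _ = np.linalg.qr(design)
    resid = seg - (seg @ q) @ q.T
    return float(np.sqrt(np.mean(resid**2)))


def estimate_alpha(series: np.ndarray, config: DFAConfig | None = None) -> DFAResult:
    """DFA scaling exponent of ``series``.

    alpha is the OLS slope of log F(n) on log n over the configured
    window sizes.  Window sizes with F(n) = 0 (e.g. from constant
    stretches) are dropped with a warning; fewer than 4 surviving points
    raise :class:`EstimationError`.
    """
    config = config or DFAConfig()
    series = np.asarray(series, dtype=float)
    if series.size < 4 * config.min_window:
        raise ValueError(
            f"series length {series.size} < 4 x min_window ({config.min_window})"
        )
    prof = profile(series)
    sizes = config.window_sizes(series.size)
    fs_vals = np.array(
        [fluctuation(prof, int(n), config.detrend_order) for n in sizes]
    )
    keep = fs_vals > 0
    dropped = tuple(int(n) for n in sizes[~keep])
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} window size(s) with zero fluctuation: {dropped}",
            RuntimeWarning,
            stacklevel=2,
        )
    sizes, fs_vals = sizes[keep], fs_vals[keep]
    if sizes.size < 4:
        raise EstimationError("fewer than 4 usable (n, F(n)) points")
    log_n = np.log10(sizes.astype(float))
    log_f = np.log10(fs_vals)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_res = float(np.sum((log_f - pred) ** 2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(
        alpha=float(slope),
        points=tuple(zip(log_n.tolist(), log_f.tolist())),
        fit_r2=r2,
        dropped=dropped,
    )
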