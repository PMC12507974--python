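"""Centre-of-pressure sway metrics.

A trial is a two-axis CoP recording — anterior–posterior ``x`` and
medial–lateral ``y``, both in mm — sampled at 200 Hz for 90 s while the
participant stands on a force plate.  The per-sample radial sway

    RS_i = sqrt(x_i**2 + y_i**2)

is computed on the absolute (uncentred) plate coordinates; a centred
variant (subtracting each axis mean first) is available via
``centered=True``.  The pipeline trims the first 4 s of each trial to
discard startle transients, averages RS per trial, decomposes sway into
slow (< 0.3 Hz) and fast (> 0.3 Hz) components with zero-phase
Butterworth filters, and flags per-trial outliers beyond +/- k SD of the
participant's mean within a condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SESSIONS",
    "CONDITIONS",
    "CoPTrial",
    "SwaySeries",
    "TrialMetrics",
    "trim_onset",
    "radial_sway",
    "mean_radial_sway",
    "band_split",
    "exclude_outliers",
]

SESSIONS = ("Sham", "LDLPFC", "RDLPFC")
CONDITIONS = ("Silent", "Easy", "Hard")


@dataclass
class CoPTrial:
    """One CoP recording with its design labels.

    ``session`` identifies the stimulation arm (Sham / LDLPFC / RDLPFC),
    ``condition`` the cognitive load (Silent / Easy / Hard), and
    ``trial_index`` the 1-based position of the trial within the session.
    """

    subject: str
    session: str
    condition: str
    trial_index: int
    fs: float
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be 1-D")
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) == 0:
            raise ValueError("empty recording")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SwaySeries:
    """A derived per-sample sway magnitude series."""

    values: np.ndarray
    fs: float
    band: str = "raw"  # "raw", "low" or "high"


@dataclass
class TrialMetrics:
    """Per-trial scalar summaries consumed by the mixed models."""

    subject: str
    session: str
    condition: str
    trial_index: int
    mean_rs: float
    mean_rs_low: float
    mean_rs_high: float
    alpha: float
    excluded: bool = False


def trim_onset(trial: CoPTrial, trim: float = 4.0) -> CoPTrial:
    """Drop the first ``trim`` seconds of a trial (startle-transient guard)."""
    if trim < 0:
        raise ValueError("trim must be non-negative")
    n_drop = int(round(trim * trial.fs))
    if abs(trim * trial.fs - n_drop) > 1e-9:
        raise ValueError("trim must be an integer number of samples")
    if n_drop >= trial.n_samples:
        raise ValueError(
            f"trim of {trim} s ({n_drop} samples) exceeds trial length "
            f"({trial.n_samples} samples)"
        )
    return replace(trial, x=trial.x[n_drop:], y=trial.y[n_drop:])


def radial_sway(
    x: Sequence[float],
    y: Sequence[float],
    fs: float = 200.0,
    centered: bool = False,
) -> SwaySeries:
    """Per-sample Euclidean CoP magnitude sqrt(x**2 + y**2).

    With ``centered=True`` each axis is mean-centred first, so RS measures
    excursion about the trial-mean CoP rather than distance from the plate
    origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if centered:
        x = x - x.mean()
        y = y - y.mean()
    return SwaySeries(values=np.hypot(x, y), fs=fs, band="raw")


def mean_radial_sway(rs: SwaySeries | np.ndarray) -> float:
    """Trial-average radial sway, the primary sway outcome."""
    values = rs.values if isinstance(rs, SwaySeries) else np.asarray(rs, dtype=float)
    if values.size == 0:
        raise ValueError("empty sway series")
    return float(values.mean())


def _butter_sos(cutoff: float, fs: float, btype: str, order: int = 2):
    return signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def _filtfilt(values: np.ndarray, sos) -> np.ndarray:
    return signal.sosfiltfilt(sos, values)


def band_split(
    trial: CoPTrial, cutoff: float = 0.3, order: int = 2
) -> tuple[CoPTrial, CoPTrial]:
    """Split a trial into slow and fast sway components at ``cutoff`` Hz.

    Each axis is filtered with a zero-phase (forward–backward) Butterworth
    filter of the given order — low-pass for the slow component, high-pass
    for the fast one.  The slow band is read as feedback-driven drift of
    the body's inertial mass, the fast band as corrective adjustments.
    Band-wise radial sway is then computed from the filtered axes.
    """
    if not (0 < cutoff < trial.fs / 2):
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff}")
    sos_lo = _butter_sos(cutoff, trial.fs, "lowpass", order)
    sos_hi = _butter_sos(cutoff, trial.fs, "highpass", order)
    low = replace(trial, x=_filtfilt(trial.x, sos_lo), y=_filtfilt(trial.y, sos_lo))
    high = replace(trial, x=_filtfilt(trial.x, sos_hi), y=_filtfilt(trial.y, sos_hi))
    return low, high


def band_split_series(
    rs: SwaySeries, cutoff: float = 0.3, order: int = 2
) -> tuple[SwaySeries, SwaySeries]:
    """Filter a radial-sway series itself into slow/fast components.

    Alternative ordering to :func:`band_split` (filter the axes, then take
    the norm).  High-pass filtering the non-negative RS series removes its
    mean, so band-wise *means* from this route hover near zero; it is kept
    behind a switch for comparability, not as the default.
    """
    if not (0 < cutoff < rs.fs / 2):
        raise ValueError(f"cutoff must lie in (0, fs/2); got {cutoff}")
    lo = _filtfilt(rs.values, _butter_sos(cutoff, rs.fs, "lowpass", order))
    hi = _filtfilt(rs.values, _butter_sos(cutoff, rs.fs, "highpass", order))
    return (
        SwaySeries(values=lo, fs=rs.fs, band="low"),
        SwaySeries(values=hi, fs=rs.fs, band="high"),
    )


def exclude_outliers(
    metrics: pd.DataFrame | Iterable[TrialMetrics],
    k: float = 2.0,
    value_col: str = "mean_rs",
    group_cols: Sequence[str] = ("subject", "condition"),
) -> pd.DataFrame:
    """Flag trials whose mean RS deviates more than ``k`` SD from the
    group mean, for an arbitrary grouping.

    Flagging is single-pass — mean and SD (n-1 denominator) are computed
    once on the full group — and every row is returned with its
    ``excluded`` flag set.  Groups of size 1, or with zero SD, are never
    flagged.  Note the sample SD bounds |z| by (n-1)/sqrt(n), so at k=2
    a group needs at least 6 members for the rule to be able to fire;
    see the pipeline config for the grouping choices offered.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.DataFrame([vars(m) for m in metrics])
    out = metrics.copy()
    grp = out.groupby(list(group_cols))[value_col]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1; NaN for singleton groups
    with np.errstate(invalid="ignore"):
        flag = (out[value_col] - mean).abs() > k * sd
    out["excluded"] = flag.fillna(False) & (sd > 0)
    return out
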