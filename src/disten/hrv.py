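"""Resting heart rate and time-domain heart rate variability.

All metrics operate on a clean RR-interval series in milliseconds.  RMSSD
and SDNN use the sample convention (n-1 denominator); pNNx counts absolute
successive differences strictly greater than x ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HRVSummary:
    mean_rri: float  # ms
    rhr: float  # bpm
    rmssd: float  # ms
    sdnn: float  # ms
    pnn5: float  # %
    pnn10: float  # %
    pnn20: float  # %


def _as_series(series) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a nonempty 1-D array of intervals")
    return x


def resting_heart_rate(series) -> float:
    """RHR in bpm: 60000 divided by the mean RR interval in ms."""
    x = _as_series(series)
    if np.any(x <= 0):
        raise ValueError("intervals must be positive")
    return 60000.0 / float(x.mean())


def rmssd(series) -> float:
    """Root mean square of successive differences (ms)."""
    x = _as_series(series)
    if x.size < 2:
        raise ValueError("rmssd needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def sdnn(series) -> float:
    """Sample standard deviation of the intervals (ms)."""
    x = _as_series(series)
    if x.size < 2:
        raise ValueError("sdnn needs at least 2 intervals")
    return float(x.std(ddof=1))


def pnnx(series, x: float) -> float:
    """Percentage of absolute successive differences strictly > x ms."""
    if x <= 0:
        raise ValueError("threshold x must be positive")
    s = _as_series(series)
    if s.size < 2:
        raise ValueError("pnnx needs at least 2 intervals")
    d = np.abs(np.diff(s))
    return 100.0 * float(np.count_nonzero(d > x)) / d.size


def hrv_summary(series) -> HRVSummary:
    x = _as_series(series)
    return HRVSummary(
        mean_rri=float(x.mean()),
        rhr=resting_heart_rate(x),
        rmssd=rmssd(x),
        sdnn=sdnn(x),
        pnn5=pnnx(x, 5.0),
        pnn10=pnnx(x, 10.0),
        pnn20=pnnx(x, 20.0),
    )
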