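"""R-peak detection and RR-interval extraction from single-lead ECG.

The detector is a standard bandpass (5-15 Hz) + squared-derivative +
moving-window-integration scheme with an adaptive amplitude threshold and a
refractory period, in the Pan-Tompkins family.  It is deliberately generic:
any beat-annotation source can be substituted by constructing an
:class:`RPeakSet` directly (the rest of the pipeline only consumes peak
indices), so detectors with sub-sample interpolation or proprietary QRS
logic plug in unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import ECGRecord


@dataclass(frozen=True)
class RPeakSet:
    """Detected R-peak sample positions (0-based) for one record."""

    indices: np.ndarray
    sampling_rate: float
    record_id: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.sampling_rate


def detect_rpeaks(
    record: ECGRecord,
    min_rri: float = 428.0,
    max_rri: float = 2000.0,
) -> RPeakSet:
    """Detect R peaks in a resting ECG record.

    Parameters
    ----------
    record : ECGRecord
        At least 5 s of signal sampled at >= 100 Hz.
    min_rri, max_rri : float
        Physiologic interval bounds in ms.  ``min_rri`` is enforced as a
        refractory period: no two returned peaks are closer than it.

    A flat (constant) trace yields an empty peak set with a warning rather
    than an exception, so cohort-level processing can record the failure
    as a QC exclusion.
    """
    x = np.asarray(record.samples, dtype=float)
    fs = record.sampling_rate
    if fs < 100.0:
        raise ValueError("sampling_rate must be >= 100 Hz")
    if x.size < 5 * fs:
        raise ValueError("record must be at least 5 s long")
    if np.ptp(x) == 0.0:
        warnings.warn(f"flat signal in record {record.record_id!r}: no peaks detected")
        return RPeakSet(np.empty(0, dtype=np.int64), fs, record.record_id)

    nyq = fs / 2.0
    b, a = signal.butter(2, [5.0 / nyq, min(15.0, 0.9 * nyq) / nyq], btype="band")
    filtered = signal.filtfilt(b, a, x)
    energy = np.gradient(filtered) ** 2
    win = max(int(round(0.15 * fs)), 1)
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = int(round(min_rri / 1000.0 * fs))
    threshold = 0.2 * np.percentile(integrated, 99)
    cand, _ = signal.find_peaks(integrated, height=threshold, distance=max(refractory, 1))
    if cand.size == 0:
        warnings.warn(f"no QRS-like activity in record {record.record_id!r}")
        return RPeakSet(np.empty(0, dtype=np.int64), fs, record.record_id)

    # refine each candidate to the local maximum of the raw signal
    half = int(round(0.1 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(np.asarray(refined, dtype=np.int64))

    # refinement may break the refractory constraint near noisy bursts
    kept: list[int] = []
    for p in peaks:
        if not kept or p - kept[-1] >= refractory:
            kept.append(int(p))
    return RPeakSet(np.asarray(kept, dtype=np.int64), fs, record.record_id)


def rri_from_peaks(peaks: RPeakSet) -> np.ndarray:
    """Convert successive peak indices to RR intervals in ms.

    Interval k is attributed to the later beat of pair (k, k+1); the
    returned series has length n_peaks - 1.
    """
    if peaks.indices.size < 2:
        raise ValueError("need at least 2 peaks to form an interval")
    return np.diff(peaks.indices) / peaks.sampling_rate * 1000.0
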