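"""Quality control of RR-interval records and cohorts.

A record cohort passes through four exclusion stages in a fixed order:

1. **RRI range** — any interval strictly above 2000 ms or strictly below
   428 ms (i.e. momentary rate outside 30-140 bpm) excludes the whole
   record.
2. **Record length** — records whose duration is more than
   ``length_sd_mult`` cohort SDs from the cohort mean duration are
   excluded (two-sided); such records typically contain gaps.
3. **Noise** — the noise score is the overall SD, across all full
   3-beat windows, of the within-window SD of the intervals; a constant
   record scores 0.  Records whose score strictly exceeds the cohort's
   ``noise_percentile``-th percentile (ceiling order statistic) are
   excluded, i.e. the top (100 - p)% by score.
4. **Pacemaker** — records flagged as having a pacemaker (metadata
   supplied with the cohort) are excluded.

Cohort-level thresholds (length mean/SD from stage-1 survivors; the noise
percentile from stage-1-2 survivors) are computed once on the incoming
cohort and frozen, so re-running QC on its own output with the frozen
thresholds excludes nothing further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QCThresholds:
    rri_min: float = 428.0  # ms
    rri_max: float = 2000.0  # ms
    length_sd_mult: float = 2.0
    noise_percentile: float = 98.0

    def __post_init__(self) -> None:
        if self.rri_min >= self.rri_max:
            raise ValueError("rri_min must be below rri_max")
        if not 0.0 < self.noise_percentile < 100.0:
            raise ValueError("noise_percentile must lie in (0, 100)")


@dataclass(frozen=True)
class FrozenCohortThresholds:
    """Cohort-level cutoffs computed once and reused verbatim."""

    length_mean_s: float
    length_sd_s: float
    noise_cutoff: float


@dataclass
class RRIRecord:
    """One record's intervals plus the metadata QC needs."""

    record_id: str
    rri: np.ndarray  # ms
    pacemaker: bool = False

    def __post_init__(self) -> None:
        self.rri = np.asarray(self.rri, dtype=float)

    @property
    def duration_s(self) -> float:
        return float(self.rri.sum()) / 1000.0

    @property
    def n_beats(self) -> int:
        return int(self.rri.size)


@dataclass(frozen=True)
class QCReport:
    record_id: str
    n_beats: int
    duration_s: float
    rri_violations: int
    noise_score: float
    excluded: bool
    reason: str  # rri_range | length_outlier | noise | pacemaker | ok


def rri_range_check(series: np.ndarray, thresholds: QCThresholds = QCThresholds()) -> int:
    """Count intervals strictly outside [rri_min, rri_max].

    The bounds themselves are acceptable: a 2000 ms interval does not
    violate the "> 2 s" rule.  Any positive count excludes the record.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be nonempty")
    return int(np.count_nonzero((x > thresholds.rri_max) | (x < thresholds.rri_min)))


def noise_score(series: np.ndarray, window: int = 3) -> float:
    """Overall SD of the moving within-window SD of the intervals (ms).

    Both the within-window SD and the outer SD use the sample (n-1)
    convention.  Scores near zero indicate a clean record; artifacts and
    ectopy inflate the score sharply.
    """
    x = np.asarray(series, dtype=float)
    if x.size < window + 1:
        raise ValueError(f"need at least {window + 1} beats, got {x.size}")
    view = np.lib.stride_tricks.sliding_window_view(x, window)
    moving_sd = view.std(axis=1, ddof=1)
    return float(moving_sd.std(ddof=1))


def _noise_cutoff(scores: np.ndarray, percentile: float) -> float:
    # ceiling order statistic: the smallest score with at least p% of the
    # cohort at or below it; records strictly above are the top (100-p)%
    return float(np.percentile(scores, percentile, method="higher"))


def cohort_qc(
    records: list[RRIRecord],
    thresholds: QCThresholds = QCThresholds(),
    frozen: FrozenCohortThresholds | None = None,
) -> tuple[list[RRIRecord], list[QCReport], FrozenCohortThresholds]:
    """Apply the staged exclusion cascade to a cohort of RRI records.

    Returns (surviving records, one report per input record, the frozen
    cohort thresholds used).  Each report carries the first triggered
    exclusion reason.  Supply ``frozen`` to reuse thresholds from an
    earlier run (required for fewer than 10 records, where cohort-level
    statistics are not meaningful).
    """
    if frozen is None and len(records) < 10:
        raise ValueError(
            "cohort-level thresholds need >= 10 records; pass explicit "
            "FrozenCohortThresholds for smaller batches"
        )

    violations = {r.record_id: rri_range_check(r.rri, thresholds) for r in records}
    stage1 = [r for r in records if violations[r.record_id] == 0]

    if frozen is None:
        durations = np.array([r.duration_s for r in stage1])
        length_mean = float(durations.mean())
        length_sd = float(durations.std(ddof=1))
    else:
        length_mean, length_sd = frozen.length_mean_s, frozen.length_sd_s

    def length_ok(r: RRIRecord) -> bool:
        return abs(r.duration_s - length_mean) <= thresholds.length_sd_mult * length_sd

    stage2 = [r for r in stage1 if length_ok(r)]
    scores = {r.record_id: noise_score(r.rri) for r in records}
    if frozen is None:
        cutoff = _noise_cutoff(
            np.array([scores[r.record_id] for r in stage2]), thresholds.noise_percentile
        )
        frozen = FrozenCohortThresholds(length_mean, length_sd, cutoff)
    else:
        cutoff = frozen.noise_cutoff

    kept: list[RRIRecord] = []
    reports: list[QCReport] = []
    for r in records:
        if violations[r.record_id] > 0:
            reason = "rri_range"
        elif not length_ok(r):
            reason = "length_outlier"
        elif scores[r.record_id] > cutoff:
            reason = "noise"
        elif r.pacemaker:
            reason = "pacemaker"
        else:
            reason = "ok"
            kept.append(r)
        reports.append(
            QCReport(
                record_id=r.record_id,
                n_beats=r.n_beats,
                duration_s=r.duration_s,
                rri_violations=violations[r.record_id],
                noise_score=scores[r.record_id],
                excluded=reason != "ok",
                reason=reason,
            )
        )
    return kept, reports, frozen


def attrition_counts(reports: list[QCReport]) -> dict[str, int]:
    """Records-per-stage accounting: input, per-reason exclusions, analyzed."""
    counts = {"input": len(reports), "rri_range": 0, "length_outlier": 0, "noise": 0, "pacemaker": 0}
    for rep in reports:
        if rep.excluded:
            counts[rep.reason] += 1
    counts["analyzed"] = len(reports) - sum(
        counts[k] for k in ("rri_range", "length_outlier", "noise", "pacemaker")
    )
    return counts


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
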