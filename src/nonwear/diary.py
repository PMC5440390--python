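"""Activity-diary model: phases, reported non-wear entries, and summaries.

The diary is the reference standard.  Participants record each waking and
sleeping phase plus the start/end time and reason of every non-wear period
(NWT; e.g. showering).  From a diary we derive

* the *assessment window* — first to last recorded time point,
* thresholded diary NWT sets (entries strictly longer than T minutes, after
  merging adjacent or overlapping entries), and
* per-participant and cohort summaries: NWT periods and minutes per 24 h and
  the proportion of reported NWT exceeding each threshold.

A "24 h unit" is (number of waking phases + number of sleeping phases) / 2,
i.e. one waking plus one sleeping phase counts as one average day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .detection import NwtPeriod, Source
from .timeline import (
    AssessmentWindow,
    Interval,
    Phase,
    PhaseKind,
    union_intervals,
    validate_phases,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DiaryRecord",
    "DiarySummary",
    "assessment_window",
    "merge_entries",
    "diary_nwt",
    "summarize",
    "summarize_cohort",
]


@dataclass
class DiaryRecord:
    """One participant's diary: ordered phases and reported non-wear entries."""

    participant_id: str
    phases: list[Phase]
    nwt_entries: list[NwtPeriod] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_phases(self.phases)
        self.phases = sorted(self.phases, key=lambda p: p.interval.start)
        for e in self.nwt_entries:
            if e.source is not Source.DIARY:
                raise ValueError("diary entries must have source='diary'")
        self.nwt_entries = sorted(self.nwt_entries, key=lambda e: e.interval.start)

    @property
    def assessment_window(self) -> AssessmentWindow:
        return assessment_window(self)


def assessment_window(d: DiaryRecord) -> AssessmentWindow:
    """Window from the earliest to the latest recorded diary time point."""
    starts = [p.interval.start for p in d.phases] + [
        e.interval.start for e in d.nwt_entries
    ]
    ends = [p.interval.end for p in d.phases] + [e.interval.end for e in d.nwt_entries]
    if not starts:
        raise ValueError(f"diary of {d.participant_id!r} has no recorded time points")
    return AssessmentWindow(Interval(min(starts), max(ends)))


def merge_entries(entries: Sequence[NwtPeriod]) -> list[NwtPeriod]:
    """Merge adjacent or overlapping reported entries into maximal periods.

    Touching entries (one ends exactly where the next starts) describe one
    continuous removal and are merged; reasons are concatenated with '; '.
    """
    ordered = sorted(entries, key=lambda e: e.interval.start)
    merged: list[NwtPeriod] = []
    for e in ordered:
        if merged and e.interval.start <= merged[-1].interval.end:
            last = merged[-1]
            reasons = [r for r in (last.reason, e.reason) if r]
            if last.reason and e.reason and last.reason != e.reason:
                logger.debug(
                    "merging overlapping diary entries with different reasons: "
                    "%r / %r",
                    last.reason,
                    e.reason,
                )
            merged[-1] = NwtPeriod(
                interval=Interval(
                    last.interval.start, max(last.interval.end, e.interval.end)
                ),
                source=Source.DIARY,
                reason="; ".join(dict.fromkeys(reasons)) or None,
            )
        else:
            merged.append(
                NwtPeriod(interval=e.interval, source=Source.DIARY, reason=e.reason)
            )
    return merged


def diary_nwt(
    d: DiaryRecord, threshold_minutes: Optional[int] = None
) -> list[NwtPeriod]:
    """Reported non-wear periods, optionally restricted to duration > threshold.

    With ``threshold_minutes=None`` all merged entries are returned regardless
    of length (the "any NWT" reference used by the minute-overlap approach 3);
    otherwise only merged entries strictly longer than the threshold, tagged
    with it.
    """
    merged = merge_entries(d.nwt_entries)
    if threshold_minutes is None:
        return merged
    return [
        NwtPeriod(
            interval=e.interval,
            source=Source.DIARY,
            threshold_minutes=threshold_minutes,
            reason=e.reason,
        )
        for e in merged
        if e.duration_minutes > threshold_minutes
    ]


@dataclass(frozen=True)
class DiarySummary:
    """Diary-based non-wear summary (per participant or pooled cohort)."""

    n_24h_units: float
    n_periods_per_24h: float
    nwt_minutes_per_24h: float
    proportion_periods_gt: dict[int, float]  # threshold -> percent of periods
    proportion_minutes_gt: dict[int, float]  # threshold -> percent of minutes

    def __post_init__(self) -> None:
        for prop in (self.proportion_periods_gt, self.proportion_minutes_gt):
            last = 100.0
            for t in sorted(prop):
                if prop[t] > last + 1e-9:
                    raise ValueError("proportions must be non-increasing in threshold")
                last = prop[t]


def _summary_from_pool(
    entries: Sequence[NwtPeriod], n_units: float, thresholds: Sequence[int]
) -> DiarySummary:
    n = len(entries)
    durations = [e.duration_minutes for e in entries]
    total_min = sum(durations)
    prop_p = {
        t: (100.0 * sum(1 for x in durations if x > t) / n) if n else 0.0
        for t in thresholds
    }
    prop_m = {
        t: (100.0 * sum(x for x in durations if x > t) / total_min)
        if total_min
        else 0.0
        for t in thresholds
    }
    return DiarySummary(
        n_24h_units=n_units,
        n_periods_per_24h=n / n_units,
        nwt_minutes_per_24h=total_min / n_units,
        proportion_periods_gt=prop_p,
        proportion_minutes_gt=prop_m,
    )


def summarize(d: DiaryRecord, thresholds: Sequence[int] = (60, 90, 120, 150, 180)) -> DiarySummary:
    """Per-participant summary of reported non-wear.

    Rates are normalised by 24 h units: (waking phases + sleeping phases) / 2.
    Proportions use merged entries; both the share of *periods* longer than
    each threshold and the share of *minutes* spent in such periods are given.
    """
    if not d.phases:
        raise ValueError("diary must contain at least one phase to summarize")
    n_units = len(d.phases) / 2.0
    return _summary_from_pool(merge_entries(d.nwt_entries), n_units, thresholds)


def summarize_cohort(
    records: Sequence[DiaryRecord],
    thresholds: Sequence[int] = (60, 90, 120, 150, 180),
    *,
    pooled: bool = True,
) -> DiarySummary:
    """Cohort summary of reported non-wear.

    With ``pooled=True`` (default) periods are pooled across participants:
    proportions are total counts over total counts, and per-24 h rates divide
    cohort totals by the cohort's summed 24 h units.  With ``pooled=False``
    the per-participant summaries are averaged with equal weight instead.
    """
    if not records:
        raise ValueError("empty cohort")
    if pooled:
        entries = [e for d in records for e in merge_entries(d.nwt_entries)]
        n_units = sum(len(d.phases) for d in records) / 2.0
        return _summary_from_pool(entries, n_units, thresholds)
    per = [summarize(d, thresholds) for d in records]
    k = len(per)
    return DiarySummary(
        n_24h_units=sum(s.n_24h_units for s in per) / k,
        n_periods_per_24h=sum(s.n_periods_per_24h for s in per) / k,
        nwt_minutes_per_24h=sum(s.nwt_minutes_per_24h for s in per) / k,
        proportion_periods_gt={
            t: sum(s.proportion_periods_gt[t] for s in per) / k for t in thresholds
        },
        proportion_minutes_gt={
            t: sum(s.proportion_minutes_gt[t] for s in per) / k for t in thresholds
        },
    )
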