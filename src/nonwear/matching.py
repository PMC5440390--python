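"""Period-level validation of detected non-wear time against the diary.

This is the fourfold-table approach: with the diary as reference, every
accelerometry-detected non-wear period and every thresholded diary period is
classified as

* ``a`` true positive  — a thresholded diary period matched by an
  accelerometry period whose minute overlap is at least 50 % of the reference
  duration;
* ``not assigned``     — a diary period with positive but sub-50 % overlap,
  excluded from sensitivity and specificity;
* ``c`` false negative — a diary period overlapping no accelerometry period;
* ``b`` false positive — an accelerometry period overlapping no thresholded
  diary period;
* ``d`` true negative  — an evaluation unit of wear in which neither source
  flags non-wear.

Sensitivity = a/(a+c), specificity = d/(b+d), each undefined when its
denominator is zero.

The set of true-negative evaluation units is an interpretation, configurable
via ``tn_units``: the sub-threshold diary entries (removals too short for the
algorithm, e.g. showering), optionally together with the wear blocks between
reported entries inside the assessment window.  The default includes the wear
blocks so that specificity is defined even for diaries whose entries all
exceed the threshold.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .detection import EpochSeries, NwtPeriod, Source, detect_nwt
from .diary import DiaryRecord, assessment_window, diary_nwt, merge_entries
from .timeline import Interval, Phase, PhaseKind, assign_phase

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "MatchTable",
    "ValidationResult",
    "classify",
    "sens_spec",
    "validate_participant",
    "validate_cohort",
]


class Stratum(str, enum.Enum):
    TOTAL = "total"
    WAKING = "waking"
    SLEEPING = "sleeping"


@dataclass(frozen=True)
class MatchTable:
    """Fourfold counts plus not-assigned periods for one classification run."""

    a_true_positive: int = 0
    b_false_positive: int = 0
    c_false_negative: int = 0
    d_true_negative: int = 0
    not_assigned: int = 0
    n_diary_periods: int = 0
    n_accel_periods: int = 0

    def __post_init__(self) -> None:
        for name in (
            "a_true_positive",
            "b_false_positive",
            "c_false_negative",
            "d_true_negative",
            "not_assigned",
            "n_diary_periods",
            "n_accel_periods",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def __add__(self, other: "MatchTable") -> "MatchTable":
        return MatchTable(
            self.a_true_positive + other.a_true_positive,
            self.b_false_positive + other.b_false_positive,
            self.c_false_negative + other.c_false_negative,
            self.d_true_negative + other.d_true_negative,
            self.not_assigned + other.not_assigned,
            self.n_diary_periods + other.n_diary_periods,
            self.n_accel_periods + other.n_accel_periods,
        )


@dataclass(frozen=True)
class ValidationResult:
    """Sensitivity/specificity derived from a match table, with context."""

    table: MatchTable
    sensitivity: Optional[float]
    specificity: Optional[float]
    stratum: Stratum = Stratum.TOTAL
    threshold_minutes: Optional[int] = None

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError("sensitivity/specificity must lie in [0, 1]")


def _wear_blocks(
    window: Interval, all_entries: Sequence[NwtPeriod]
) -> list[Interval]:
    """Maximal wear intervals: the assessment window minus all reported entries."""
    blocks: list[Interval] = []
    cursor = window.start
    for e in merge_entries(all_entries):
        lo = max(e.interval.start, window.start)
        if cursor < lo:
            blocks.append(Interval(cursor, lo))
        cursor = max(cursor, min(e.interval.end, window.end))
    if cursor < window.end:
        blocks.append(Interval(cursor, window.end))
    return blocks


def classify(
    diary_periods: Sequence[NwtPeriod],
    accel_periods: Sequence[NwtPeriod],
    sub_threshold_entries: Sequence[NwtPeriod] = (),
    wear_blocks: Sequence[Interval] = (),
    *,
    overlap_denominator: str = "diary",
) -> MatchTable:
    """Classify period pairs into the fourfold table.

    Parameters
    ----------
    diary_periods
        Thresholded diary non-wear periods (the reference).
    accel_periods
        Accelerometry-detected periods at the same threshold.
    sub_threshold_entries
        Reported entries too short for the threshold; true-negative candidates.
    wear_blocks
        Additional true-negative candidate intervals (diary wear time).
    overlap_denominator
        Reference length for the 50 % rule: ``"diary"`` (default),
        ``"accelerometry"``, or ``"shorter"`` of the pair.

    Matching is greedy on minute overlap: candidate pairs are visited in order
    of decreasing overlap (earlier diary period on ties) and each period is
    matched at most once.
    """
    if overlap_denominator not in ("diary", "accelerometry", "shorter"):
        raise ValueError(f"unknown overlap_denominator: {overlap_denominator!r}")

    pairs: list[tuple[int, int, int]] = []  # (overlap, diary idx, accel idx)
    for i, dp in enumerate(diary_periods):
        for j, ap in enumerate(accel_periods):
            m = dp.interval.overlap_minutes(ap.interval)
            if m > 0:
                pairs.append((m, i, j))
    pairs.sort(key=lambda t: (-t[0], diary_periods[t[1]].interval.start))

    matched: dict[int, tuple[int, int]] = {}  # diary idx -> (overlap, accel idx)
    taken_accel: set[int] = set()
    for m, i, j in pairs:
        if i in matched or j in taken_accel:
            continue
        matched[i] = (m, j)
        taken_accel.add(j)

    a = c = not_assigned = 0
    for i, dp in enumerate(diary_periods):
        if i in matched:
            m, j = matched[i]
            if overlap_denominator == "diary":
                ref = dp.duration_minutes
            elif overlap_denominator == "accelerometry":
                ref = accel_periods[j].duration_minutes
            else:
                ref = min(dp.duration_minutes, accel_periods[j].duration_minutes)
            if 2 * m >= ref:
                a += 1
            else:
                not_assigned += 1
        elif any(dp.interval.overlaps(ap.interval) for ap in accel_periods):
            # lost its only overlapping partner(s) to greedy assignment
            not_assigned += 1
            logger.debug(
                "diary period %s shares accelerometry overlap already assigned "
                "elsewhere; recorded as not assigned",
                dp.interval,
            )
        else:
            c += 1

    b = sum(
        1
        for ap in accel_periods
        if not any(ap.interval.overlaps(dp.interval) for dp in diary_periods)
    )

    accel_ivs = [ap.interval for ap in accel_periods]
    d = sum(
        1
        for unit in [e.interval for e in sub_threshold_entries] + list(wear_blocks)
        if not any(unit.overlaps(iv) for iv in accel_ivs)
    )

    return MatchTable(
        a_true_positive=a,
        b_false_positive=b,
        c_false_negative=c,
        d_true_negative=d,
        not_assigned=not_assigned,
        n_diary_periods=len(diary_periods),
        n_accel_periods=len(accel_periods),
    )


def sens_spec(
    t: MatchTable,
    stratum: Stratum = Stratum.TOTAL,
    threshold_minutes: Optional[int] = None,
) -> ValidationResult:
    """Sensitivity a/(a+c) and specificity d/(b+d); ``None`` on zero denominators."""
    a, b = t.a_true_positive, t.b_false_positive
    c, d = t.c_false_negative, t.d_true_negative
    sens = a / (a + c) if (a + c) > 0 else None
    spec = d / (b + d) if (b + d) > 0 else None
    return ValidationResult(
        table=t,
        sensitivity=sens,
        specificity=spec,
        stratum=Stratum(stratum),
        threshold_minutes=threshold_minutes,
    )


def _stratum_filter(
    periods: Sequence[NwtPeriod], phases: Sequence[Phase], stratum: Stratum
) -> list[NwtPeriod]:
    if stratum is Stratum.TOTAL:
        return list(periods)
    kind = PhaseKind(stratum.value)
    return [
        p for p in periods if assign_phase(p.interval, phases) is kind
    ]


def validate_participant(
    diary: DiaryRecord,
    series: EpochSeries | Sequence[EpochSeries],
    threshold_minutes: int,
    stratum: Stratum = Stratum.TOTAL,
    *,
    tn_units: str = "entries+wear_blocks",
    overlap_denominator: str = "diary",
) -> MatchTable:
    """Run the full period-level classification for one participant.

    Detects accelerometry non-wear at the threshold, derives the thresholded
    diary reference, attributes every period and true-negative unit to its
    diary phase (majority of minutes) and classifies within the requested
    stratum.  ``tn_units`` selects the true-negative evaluation units:
    ``"entries"`` for sub-threshold diary entries only, or
    ``"entries+wear_blocks"`` (default) to add the wear blocks between
    reported entries.
    """
    if tn_units not in ("entries", "entries+wear_blocks"):
        raise ValueError(f"unknown tn_units: {tn_units!r}")
    stratum = Stratum(stratum)
    segments = [series] if isinstance(series, EpochSeries) else list(series)
    accel = [
        p for seg in segments for p in detect_nwt(seg, threshold_minutes)
    ]
    diary_p = diary_nwt(diary, threshold_minutes)
    all_entries = merge_entries(diary.nwt_entries)
    sub = [e for e in all_entries if e.duration_minutes <= threshold_minutes]

    window = assessment_window(diary).interval
    blocks: list[Interval] = []
    if tn_units == "entries+wear_blocks":
        blocks = _wear_blocks(window, all_entries)

    phases = diary.phases
    diary_p = _stratum_filter(diary_p, phases, stratum)
    accel = _stratum_filter(accel, phases, stratum)
    sub = _stratum_filter(sub, phases, stratum)
    if stratum is not Stratum.TOTAL:
        kind = PhaseKind(stratum.value)
        blocks = [b for b in blocks if assign_phase(b, phases) is kind]

    return classify(
        diary_p,
        accel,
        sub,
        blocks,
        overlap_denominator=overlap_denominator,
    )


def validate_cohort(
    participants: Sequence[tuple[DiaryRecord, EpochSeries | Sequence[EpochSeries]]],
    thresholds: Sequence[int] = (60, 90, 120, 150, 180),
    strata: Sequence[Stratum] = (Stratum.TOTAL, Stratum.WAKING, Stratum.SLEEPING),
    *,
    tn_units: str = "entries+wear_blocks",
    overlap_denominator: str = "diary",
):
    """Pooled cohort validation: one result row per stratum and threshold.

    Tables are summed over participants before computing sensitivity and
    specificity, so each cell reflects the cohort's pooled period counts.
    Returns a :class:`pandas.DataFrame`.
    """
    import pandas as pd

    rows = []
    for stratum in strata:
        stratum = Stratum(stratum)
        for t in thresholds:
            pooled = MatchTable()
            for diary, series in participants:
                pooled = pooled + validate_participant(
                    diary,
                    series,
                    t,
                    stratum,
                    tn_units=tn_units,
                    overlap_denominator=overlap_denominator,
                )
            res = sens_spec(pooled, stratum, t)
            rows.append(
                {
                    "stratum": stratum.value,
                    "threshold_minutes": t,
                    "n_diary_periods": pooled.n_diary_periods,
                    "n_accel_periods": pooled.n_accel_periods,
                    "a": pooled.a_true_positive,
                    "b": pooled.b_false_positive,
                    "c": pooled.c_false_negative,
                    "d": pooled.d_true_negative,
                    "not_assigned": pooled.not_assigned,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
            )
    return pd.DataFrame(rows)
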