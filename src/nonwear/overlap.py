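"""Minute-by-minute overlap decomposition of non-wear time (approaches 2 and 3).

Instead of counting matched periods, these analyses compare non-wear *minutes*.
Within the assessment window the minutes flagged by the diary and by the
accelerometry algorithm form two sets; their union is the *potential total*
non-wear time and decomposes exactly into

* both         — minutes flagged by diary *and* accelerometry (the overlap),
* diary only   — reported but not detected,
* accel. only  — detected but not reported.

Approach 2 thresholds both sources at the same T; approach 3 keeps *any*
reported diary non-wear regardless of length while accelerometry still uses
the T-min algorithm, quantifying how much reported non-wear the algorithms
can see at all.

Stratum restriction (waking/sleeping) happens at the minute level by default —
the decomposition is intersected with the stratum's diary-phase minutes — with
a period-level alternative (keep whole periods attributed to the stratum by
majority of minutes) behind the ``stratum_restriction`` flag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detection import EpochSeries, NwtPeriod, detect_nwt
from .diary import DiaryRecord, assessment_window, diary_nwt
from .matching import Stratum, _stratum_filter
from .timeline import Interval, PhaseKind, minute_mask

__all__ = [
    "DiaryMode",
    "OverlapDecomposition",
    "decompose",
    "participant_minute_masks",
    "run_approach2",
    "run_approach3",
    "overlap_cohort",
]


class DiaryMode(str, enum.Enum):
    THRESHOLDED = "thresholded"  # approach 2: diary entries > T only
    ANY = "any"  # approach 3: all reported entries


@dataclass(frozen=True)
class OverlapDecomposition:
    """Minutes and shares of both / diary-only / accelerometry-only non-wear.

    Percentages are relative to the potential total (the union) and are
    ``None`` when the union is empty.  ``n_diary_periods``/``n_accel_periods``
    count the contributing periods, mirroring the published table layout.
    """

    minutes_both: int
    minutes_diary_only: int
    minutes_accel_only: int
    potential_total: int
    pct_both: Optional[float]
    pct_diary_only: Optional[float]
    pct_accel_only: Optional[float]
    stratum: Stratum = Stratum.TOTAL
    threshold_minutes: Optional[int] = None
    diary_mode: DiaryMode = DiaryMode.THRESHOLDED
    minutes_diary_total: int = 0
    minutes_accel_total: int = 0
    n_diary_periods: int = 0
    n_accel_periods: int = 0

    def __post_init__(self) -> None:
        if (
            self.minutes_both + self.minutes_diary_only + self.minutes_accel_only
            != self.potential_total
        ):
            raise ValueError("overlap components must sum to the potential total")
        if self.potential_total > 0:
            s = self.pct_both + self.pct_diary_only + self.pct_accel_only
            if abs(s - 100.0) > 0.1:
                raise ValueError(f"percentages sum to {s}, expected 100")


def decompose(
    diary_mask: np.ndarray,
    accel_mask: np.ndarray,
    *,
    stratum: Stratum = Stratum.TOTAL,
    threshold_minutes: Optional[int] = None,
    diary_mode: DiaryMode = DiaryMode.THRESHOLDED,
    n_diary_periods: int = 0,
    n_accel_periods: int = 0,
) -> OverlapDecomposition:
    """Decompose two minute masks over a common window grid.

    Masks must share their grid (same window, index = minutes since window
    start).  The union is the potential total non-wear; an empty union yields
    undefined (``None``) percentages.
    """
    if diary_mask.shape != accel_mask.shape:
        raise ValueError("minute masks must share one window grid")
    both = int(np.count_nonzero(diary_mask & accel_mask))
    d_only = int(np.count_nonzero(diary_mask & ~accel_mask))
    a_only = int(np.count_nonzero(accel_mask & ~diary_mask))
    total = both + d_only + a_only
    if total:
        pct = lambda x: 100.0 * x / total
        pcts = (pct(both), pct(d_only), pct(a_only))
    else:
        pcts = (None, None, None)
    return OverlapDecomposition(
        minutes_both=both,
        minutes_diary_only=d_only,
        minutes_accel_only=a_only,
        potential_total=total,
        pct_both=pcts[0],
        pct_diary_only=pcts[1],
        pct_accel_only=pcts[2],
        stratum=Stratum(stratum),
        threshold_minutes=threshold_minutes,
        diary_mode=DiaryMode(diary_mode),
        minutes_diary_total=int(np.count_nonzero(diary_mask)),
        minutes_accel_total=int(np.count_nonzero(accel_mask)),
        n_diary_periods=n_diary_periods,
        n_accel_periods=n_accel_periods,
    )


def participant_minute_masks(
    diary: DiaryRecord,
    series: EpochSeries | Sequence[EpochSeries],
    threshold_minutes: int,
    stratum: Stratum = Stratum.TOTAL,
    *,
    diary_mode: DiaryMode = DiaryMode.THRESHOLDED,
    stratum_restriction: str = "minute",
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Diary and accelerometry non-wear minute masks over the assessment window.

    Returns ``(diary_mask, accel_mask, n_diary_periods, n_accel_periods)``.
    Period counts refer to periods contributing at least one minute to the
    stratum-restricted masks.
    """
    if stratum_restriction not in ("minute", "period"):
        raise ValueError(f"unknown stratum_restriction: {stratum_restriction!r}")
    stratum = Stratum(stratum)
    diary_mode = DiaryMode(diary_mode)
    window = assessment_window(diary).interval
    segments = [series] if isinstance(series, EpochSeries) else list(series)

    d_periods = diary_nwt(
        diary, None if diary_mode is DiaryMode.ANY else threshold_minutes
    )
    a_periods = [p for s in segments for p in detect_nwt(s, threshold_minutes)]

    if stratum is Stratum.TOTAL:
        d_mask = minute_mask([p.interval for p in d_periods], window)
        a_mask = minute_mask([p.interval for p in a_periods], window)
    elif stratum_restriction == "period":
        d_periods = _stratum_filter(d_periods, diary.phases, stratum)
        a_periods = _stratum_filter(a_periods, diary.phases, stratum)
        d_mask = minute_mask([p.interval for p in d_periods], window)
        a_mask = minute_mask([p.interval for p in a_periods], window)
    else:
        kind = PhaseKind(stratum.value)
        phase_mask = minute_mask(
            [ph.interval for ph in diary.phases if ph.kind is kind], window
        )
        d_mask = minute_mask([p.interval for p in d_periods], window) & phase_mask
        a_mask = minute_mask([p.interval for p in a_periods], window) & phase_mask
        d_periods = [
            p
            for p in d_periods
            if np.any(minute_mask([p.interval], window) & phase_mask)
        ]
        a_periods = [
            p
            for p in a_periods
            if np.any(minute_mask([p.interval], window) & phase_mask)
        ]
    return d_mask, a_mask, len(d_periods), len(a_periods)


def run_approach2(
    diary: DiaryRecord,
    series: EpochSeries | Sequence[EpochSeries],
    threshold_minutes: int,
    stratum: Stratum = Stratum.TOTAL,
    *,
    stratum_restriction: str = "minute",
) -> OverlapDecomposition:
    """Overlap decomposition with both sources thresholded at T."""
    d_mask, a_mask, nd, na = participant_minute_masks(
        diary,
        series,
        threshold_minutes,
        stratum,
        diary_mode=DiaryMode.THRESHOLDED,
        stratum_restriction=stratum_restriction,
    )
    return decompose(
        d_mask,
        a_mask,
        stratum=stratum,
        threshold_minutes=threshold_minutes,
        diary_mode=DiaryMode.THRESHOLDED,
        n_diary_periods=nd,
        n_accel_periods=na,
    )


def run_approach3(
    diary: DiaryRecord,
    series: EpochSeries | Sequence[EpochSeries],
    threshold_minutes: int,
    stratum: Stratum = Stratum.TOTAL,
    *,
    stratum_restriction: str = "minute",
) -> OverlapDecomposition:
    """Overlap decomposition with any-length diary non-wear as reference."""
    d_mask, a_mask, nd, na = participant_minute_masks(
        diary,
        series,
        threshold_minutes,
        stratum,
        diary_mode=DiaryMode.ANY,
        stratum_restriction=stratum_restriction,
    )
    return decompose(
        d_mask,
        a_mask,
        stratum=stratum,
        threshold_minutes=threshold_minutes,
        diary_mode=DiaryMode.ANY,
        n_diary_periods=nd,
        n_accel_periods=na,
    )


def overlap_cohort(
    participants: Sequence[tuple[DiaryRecord, EpochSeries | Sequence[EpochSeries]]],
    thresholds: Sequence[int] = (60, 90, 120, 150, 180),
    strata: Sequence[Stratum] = (Stratum.TOTAL, Stratum.WAKING, Stratum.SLEEPING),
    *,
    diary_mode: DiaryMode = DiaryMode.THRESHOLDED,
    stratum_restriction: str = "minute",
):
    """Pooled cohort overlap decomposition, one row per stratum and threshold.

    Minutes and period counts are summed over participants; the percentages
    are recomputed on the pooled minutes.  Returns a :class:`pandas.DataFrame`.
    """
    import pandas as pd

    diary_mode = DiaryMode(diary_mode)
    rows = []
    for stratum in strata:
        stratum = Stratum(stratum)
        for t in thresholds:
            both = d_only = a_only = 0
            d_tot = a_tot = nd = na = 0
            for diary, series in participants:
                d_mask, a_mask, pnd, pna = participant_minute_masks(
                    diary,
                    series,
                    t,
                    stratum,
                    diary_mode=diary_mode,
                    stratum_restriction=stratum_restriction,
                )
                both += int(np.count_nonzero(d_mask & a_mask))
                d_only += int(np.count_nonzero(d_mask & ~a_mask))
                a_only += int(np.count_nonzero(a_mask & ~d_mask))
                d_tot += int(np.count_nonzero(d_mask))
                a_tot += int(np.count_nonzero(a_mask))
                nd += pnd
                na += pna
            total = both + d_only + a_only
            rows.append(
                {
                    "stratum": stratum.value,
                    "threshold_minutes": t,
                    "diary_mode": diary_mode.value,
                    "diary_total_min": d_tot,
                    "n_diary_periods": nd,
                    "accel_total_min": a_tot,
                    "n_accel_periods": na,
                    "potential_total_min": total,
                    "pct_both": 100.0 * both / total if total else None,
                    "pct_diary_only": 100.0 * d_only / total if total else None,
                    "pct_accel_only": 100.0 * a_only / total if total else None,
                }
            )
    return pd.DataFrame(rows)
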