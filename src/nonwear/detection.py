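"""Run-length detection of non-wear time (NWT) in epoch count series.

A recording is a contiguous stream of fixed-length epochs (60 s by default)
carrying non-negative integer "vector magnitude" activity counts — the rounded
Euclidean norm of the three axis counts.  An epoch is *zero* iff its vector
magnitude count is 0, which happens exactly when no axis registered any
acceleration.

The detector flags every maximal run of consecutive zero epochs whose duration
is *strictly greater* than a threshold T minutes (the "T-min algorithm").
A single non-zero epoch terminates a run: no interruptions are tolerated by
default.  An optional interruption tolerance exists for exploratory use but is
off by default and not part of the validated configuration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .timeline import MINUTE, Interval, PhaseKind

__all__ = [
    "Source",
    "EpochSeries",
    "NwtPeriod",
    "vector_magnitude",
    "detect_nwt",
]


class Source(str, enum.Enum):
    """Where a non-wear period was identified."""

    ACCELEROMETRY = "accelerometry"
    DIARY = "diary"


@dataclass
class EpochSeries:
    """A contiguous per-participant stream of epoch counts.

    Parameters
    ----------
    participant_id
        Identifier of the wearer.
    epoch_start
        Timestamp of the first epoch (minute resolution).
    counts
        Non-negative integer vector-magnitude counts, one per epoch.
    epoch_length
        Epoch duration in seconds; 60 throughout the analyses here.
    placement
        Optional wear location annotation (``hip``, ``wrist`` or ``mixed``).

    Timestamp gaps must split the input into separate ``EpochSeries`` segments
    (the readers in :mod:`nonwear.io` do this); zero runs never span segments.
    """

    participant_id: str
    epoch_start: pd.Timestamp
    counts: np.ndarray
    epoch_length: int = 60
    placement: Optional[str] = None

    def __post_init__(self) -> None:
        self.epoch_start = pd.Timestamp(self.epoch_start).floor("min")
        arr = np.asarray(self.counts)
        if arr.size == 0:
            raise ValueError("empty epoch series")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("epoch counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("epoch counts must be non-negative")
        self.counts = arr.astype(np.int64, copy=False)
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.placement is not None and self.placement not in (
            "hip",
            "wrist",
            "mixed",
        ):
            raise ValueError(f"unknown placement: {self.placement!r}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def interval(self) -> Interval:
        end = self.epoch_start + pd.Timedelta(seconds=self.epoch_length * len(self))
        return Interval(self.epoch_start, end)


@dataclass(frozen=True)
class NwtPeriod:
    """One non-wear period, detected from counts or reported in a diary."""

    interval: Interval
    source: Source
    threshold_minutes: Optional[int] = None
    phase: Optional[PhaseKind] = None
    reason: Optional[str] = None
    at_gap: bool = False  # run abuts a segment boundary; observed length is a lower bound

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        if self.phase is not None:
            object.__setattr__(self, "phase", PhaseKind(self.phase))
        if (
            self.threshold_minutes is not None
            and self.interval.duration_minutes <= self.threshold_minutes
        ):
            raise ValueError(
                f"period of {self.interval.duration_minutes} min does not exceed "
                f"threshold {self.threshold_minutes} min"
            )

    @property
    def duration_minutes(self) -> int:
        return self.interval.duration_minutes

    def with_phase(self, phase: Optional[PhaseKind]) -> "NwtPeriod":
        return NwtPeriod(
            interval=self.interval,
            source=self.source,
            threshold_minutes=self.threshold_minutes,
            phase=phase,
            reason=self.reason,
            at_gap=self.at_gap,
        )


def vector_magnitude(x: int, y: int, z: int) -> int:
    """Rounded Euclidean norm of the three axis counts of one epoch.

    Zero iff all three axes are zero: any positive integer axis count gives a
    norm of at least 1, so wear epochs can never collapse to zero by rounding.
    """
    for v in (x, y, z):
        if v < 0:
            raise ValueError("axis counts must be non-negative")
    return round(math.sqrt(x * x + y * y + z * z))


def _zero_runs(zero: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as (start, stop) epoch indices."""
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_nwt(
    series: EpochSeries,
    threshold_minutes: int,
    *,
    interruption_tolerance_epochs: int = 0,
) -> list[NwtPeriod]:
    """Detect non-wear periods as zero-count runs strictly longer than a threshold.

    Parameters
    ----------
    series
        Contiguous epoch count series (validated on construction).
    threshold_minutes
        Minimal length T; a run qualifies iff its duration exceeds T strictly,
        so at 60 s epochs a ">60 min" run needs at least 61 zero epochs.
    interruption_tolerance_epochs
        If positive, bridge gaps of at most this many consecutive non-zero
        epochs between zero runs before applying the threshold.  Default 0:
        a single non-zero epoch terminates a run.

    Returns
    -------
    list of NwtPeriod
        Time-ordered, non-overlapping periods with ``source=accelerometry``.
        Runs touching the first or last epoch of the segment carry
        ``at_gap=True`` since their true extent may continue beyond the data.
    """
    if threshold_minutes < 1:
        raise ValueError("threshold_minutes must be >= 1")
    if (threshold_minutes * 60) % series.epoch_length != 0:
        raise ValueError(
            f"threshold of {threshold_minutes} min is not a whole number of "
            f"{series.epoch_length}-s epochs"
        )
    zero = series.counts == 0
    runs = _zero_runs(zero)

    if interruption_tolerance_epochs > 0 and len(runs) > 1:
        bridged: list[tuple[int, int]] = [runs[0]]
        for start, stop in runs[1:]:
            if start - bridged[-1][1] <= interruption_tolerance_epochs:
                bridged[-1] = (bridged[-1][0], stop)
            else:
                bridged.append((start, stop))
        runs = bridged

    epoch_td = pd.Timedelta(seconds=series.epoch_length)
    periods: list[NwtPeriod] = []
    n = len(series)
    for start, stop in runs:
        duration_min = (stop - start) * series.epoch_length / 60.0
        if duration_min > threshold_minutes:
            periods.append(
                NwtPeriod(
                    interval=Interval(
                        series.epoch_start + start * epoch_td,
                        series.epoch_start + stop * epoch_td,
                    ),
                    source=Source.ACCELEROMETRY,
                    threshold_minutes=threshold_minutes,
                    at_gap=(start == 0 or stop == n),
                )
            )
    return periods
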