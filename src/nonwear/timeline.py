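"""Minute-resolution interval algebra and diary-phase segmentation.

All timestamps are naive local times truncated to whole minutes, and all
intervals are half-open ``[start, end)``.  The half-open convention means a
minute belongs to exactly one of two abutting intervals, so durations add up
without double counting and every duration is an integral number of minutes.

This module is the shared plumbing for the rest of the package: detected and
reported non-wear periods, diary waking/sleeping phases and the per-participant
assessment window are all expressed as :class:`Interval` objects, and the
minute-by-minute computations downstream reduce to boolean masks over the
minute grid built here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MINUTE = pd.Timedelta(minutes=1)

__all__ = [
    "MINUTE",
    "Interval",
    "PhaseKind",
    "Phase",
    "AssessmentWindow",
    "intersect",
    "union_intervals",
    "minutes_in",
    "minute_mask",
    "assign_phase",
    "validate_phases",
]


def _floor_minute(ts) -> pd.Timestamp:
    """Truncate a timestamp-like value to minute resolution (seconds dropped)."""
    return pd.Timestamp(ts).floor("min")


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open time interval ``[start, end)`` on the one-minute grid."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", _floor_minute(self.start))
        object.__setattr__(self, "end", _floor_minute(self.end))
        if not self.start < self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def duration_minutes(self) -> int:
        return int((self.end - self.start) // MINUTE)

    def contains(self, ts) -> bool:
        ts = _floor_minute(ts)
        return self.start <= ts < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def overlap_minutes(self, other: "Interval") -> int:
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, int((hi - lo) // MINUTE))

    def shift(self, minutes: int) -> "Interval":
        delta = minutes * MINUTE
        return Interval(self.start + delta, self.end + delta)

    def __repr__(self) -> str:  # compact, log-friendly
        return f"Interval[{self.start:%Y-%m-%d %H:%M} .. {self.end:%Y-%m-%d %H:%M})"


class PhaseKind(str, enum.Enum):
    """Diary-derived stratum of the recording timeline."""

    WAKING = "waking"
    SLEEPING = "sleeping"


@dataclass(frozen=True)
class Phase:
    """One diary-recorded waking or sleeping phase."""

    interval: Interval
    kind: PhaseKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PhaseKind(self.kind))


@dataclass(frozen=True)
class AssessmentWindow:
    """Per-participant analysis window: first to last recorded diary time point."""

    interval: Interval

    @property
    def duration_minutes(self) -> int:
        return self.interval.duration_minutes


def intersect(a: Interval, b: Interval) -> Optional[Interval]:
    """Maximal interval contained in both ``a`` and ``b``, or ``None`` if disjoint.

    Half-open semantics: ``[0, 50) ∩ [50, 100)`` is empty.
    """
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if lo < hi:
        return Interval(lo, hi)
    return None


def union_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or abutting intervals into maximal disjoint intervals."""
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ordered:
        if merged and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def minutes_in(intervals: Sequence[Interval], window: Interval) -> int:
    """Distinct minutes covered by the union of ``intervals``, clipped to ``window``."""
    total = 0
    for iv in union_intervals(intervals):
        clipped = intersect(iv, window)
        if clipped is not None:
            total += clipped.duration_minutes
    return total


def minute_mask(intervals: Iterable[Interval], window: Interval) -> np.ndarray:
    """Boolean mask over the window's minute grid, True where any interval covers.

    Index ``i`` of the mask corresponds to the minute
    ``[window.start + i min, window.start + (i+1) min)``.
    """
    n = window.duration_minutes
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        lo = int((max(iv.start, window.start) - window.start) // MINUTE)
        hi = int((min(iv.end, window.end) - window.start) // MINUTE)
        if lo < hi:
            mask[lo:hi] = True
    return mask


def validate_phases(phases: Sequence[Phase]) -> None:
    """Check that one participant's phases are time-ordered and non-overlapping."""
    ordered = sorted(phases, key=lambda p: p.interval.start)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.interval.start < prev.interval.end:
            raise ValueError(
                f"phases overlap: {prev.interval} and {nxt.interval}"
            )


def assign_phase(
    p: Interval, phases: Sequence[Phase], *, tie: str = "start"
) -> Optional[PhaseKind]:
    """Attribute an interval to the waking or sleeping stratum.

    The interval is assigned to the phase kind covering the majority of its
    minutes.  On an exact tie the kind of the phase containing the interval's
    first minute wins (``tie="start"``); if no phase contains the start the
    earliest overlapping phase decides.  Returns ``None`` when the interval
    overlaps no phase at all (minutes outside every diary phase belong to the
    total-time stratum only).
    """
    if tie not in ("start",):
        raise ValueError(f"unknown tie rule: {tie!r}")
    votes = {PhaseKind.WAKING: 0, PhaseKind.SLEEPING: 0}
    overlapping: list[Phase] = []
    for ph in phases:
        m = p.overlap_minutes(ph.interval)
        if m > 0:
            votes[ph.kind] += m
            overlapping.append(ph)
    if not overlapping:
        return None
    if votes[PhaseKind.WAKING] > votes[PhaseKind.SLEEPING]:
        return PhaseKind.WAKING
    if votes[PhaseKind.SLEEPING] > votes[PhaseKind.WAKING]:
        return PhaseKind.SLEEPING
    # exact tie: phase containing the start minute, else earliest overlap
    for ph in overlapping:
        if ph.interval.contains(p.start):
            return ph.kind
    return min(overlapping, key=lambda ph: ph.interval.start).kind
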