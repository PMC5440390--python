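"""Synthetic 24 h-accelerometry cohorts with ground-truth and reported diaries.

The generator emulates the data structure the validation analyses assume: per
participant, several days of contiguous 60 s-epoch vector-magnitude counts,
diary waking/sleeping phases, device-removal events (true non-wear, zeroing
the counts) and wear-time motionless runs (true wear with zero counts — brief
sedentary spells while awake and longer still periods during sleep, the latter
heavier-tailed for hip than for wrist placement).  The *reported* diary is the
ground truth perturbed by a reporting-error model (start/end jitter and
rounding to a few minutes), mirroring how participants round times.

Default rates are calibrated to what field diaries show: a bit under one
removal per 24 h, with roughly 85 % of removals shorter than 60 minutes
(showering, changing clothes), so that only the small long-removal minority is
even visible to run-length algorithms of 60 minutes and more.

Distribution families (Poisson event counts, log-normal durations) are
pragmatic choices for skewed positive durations; all parameters are exposed on
:class:`GeneratorConfig`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import EpochSeries, NwtPeriod, Source
from .diary import DiaryRecord
from .timeline import MINUTE, Interval, Phase, PhaseKind

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SyntheticParticipant",
    "generate",
    "scenario_presets",
]

_ORIGIN = pd.Timestamp("2017-05-01 00:00")

DEFAULT_REASONS = (
    "showering",
    "personal hygiene",
    "changing clothes",
    "water activities, sauna, or high contact sports",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Durations are minutes, rates are events per unit stated in the field name.
    ``removal_duration_lognorm`` is (mu, sigma) of a log-normal on minutes;
    the default (ln 25, 0.75) puts ≈ 12 % of removals above 60 minutes.
    """

    n_participants: int = 47
    days_per_participant: int = 7
    wake_start_hour: float = 7.0
    wake_mean_h: float = 16.0
    sleep_mean_h: float = 8.0
    schedule_jitter_min: float = 30.0

    removal_rate_per_24h: float = 0.85
    removal_duration_lognorm: tuple[float, float] = (math.log(25.0), 0.75)
    removal_min_duration: int = 5
    removal_max_duration: int = 480
    removal_waking_fraction: float = 0.9
    removal_reasons: tuple[str, ...] = DEFAULT_REASONS

    sleep_motionless_runs_per_night: float = 3.0
    sleep_motionless_lognorm: tuple[float, float] = (math.log(50.0), 0.7)
    waking_zero_runs_per_day: float = 2.0
    waking_zero_lognorm: tuple[float, float] = (math.log(10.0), 0.6)
    max_wear_zero_run_min: Optional[int] = 400

    counts_lognorm: tuple[float, float] = (math.log(800.0), 1.0)

    diary_rounding_min: int = 5
    diary_jitter_sd_min: float = 5.0

    placement: str = "hip"
    layout: Optional[str] = None  # deterministic layouts, e.g. "worked_example"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.days_per_participant < 1:
            raise ValueError("cohort and recording sizes must be positive")
        for name in (
            "removal_rate_per_24h",
            "sleep_motionless_runs_per_night",
            "waking_zero_runs_per_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.removal_waking_fraction <= 1.0:
            raise ValueError("removal_waking_fraction must lie in [0, 1]")
        if self.diary_rounding_min < 1:
            raise ValueError("diary_rounding_min must be >= 1")

    @property
    def expected_prop_removals_gt_60(self) -> float:
        """Configured probability that a removal exceeds 60 min (log-normal tail)."""
        mu, sigma = self.removal_duration_lognorm
        z = (math.log(60.0) - mu) / sigma
        return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass
class SyntheticParticipant:
    """One simulated participant: counts, exact diary, and reported diary."""

    series: EpochSeries
    truth: DiaryRecord
    reported: DiaryRecord


def _draw_minutes(rng: np.random.Generator, lognorm: tuple[float, float]) -> int:
    mu, sigma = lognorm
    return max(1, int(round(rng.lognormal(mu, sigma))))


class _Placer:
    """Places zero runs in a participant's minute grid without letting two
    runs touch, so each placed run stays a maximal zero run of exactly the
    intended length."""

    def __init__(self, n_minutes: int) -> None:
        # occupied includes a one-minute margin around every placed run
        self.occupied = np.zeros(n_minutes, dtype=bool)
        self.n = n_minutes

    def try_place(
        self, rng: np.random.Generator, lo: int, hi: int, duration: int
    ) -> Optional[tuple[int, int]]:
        """Place a run of ``duration`` minutes inside grid slice [lo, hi)."""
        if duration > hi - lo:
            return None
        for _ in range(20):
            s = int(rng.integers(lo, hi - duration + 1))
            e = s + duration
            g0, g1 = max(0, s - 1), min(self.n, e + 1)
            if not self.occupied[g0:g1].any():
                self.occupied[g0:g1] = True
                return s, e
        return None


def _build_phases(
    rng: np.random.Generator, cfg: GeneratorConfig, start: pd.Timestamp
) -> list[Phase]:
    phases: list[Phase] = []
    t = start
    for _ in range(cfg.days_per_participant):
        for mean_h, kind in (
            (cfg.wake_mean_h, PhaseKind.WAKING),
            (cfg.sleep_mean_h, PhaseKind.SLEEPING),
        ):
            dur = max(60, int(round(mean_h * 60 + rng.normal(0, cfg.schedule_jitter_min))))
            phases.append(Phase(Interval(t, t + dur * MINUTE), kind))
            t = t + dur * MINUTE
    return phases


def _report_entry(
    rng: np.random.Generator, cfg: GeneratorConfig, iv: Interval, window: Interval
) -> Interval:
    """Perturb a true removal interval by the diary-error model."""
    g = cfg.diary_rounding_min

    def perturb(ts: pd.Timestamp) -> pd.Timestamp:
        jitter = rng.normal(0, cfg.diary_jitter_sd_min) if cfg.diary_jitter_sd_min else 0.0
        m = (ts - _ORIGIN) // MINUTE + jitter
        return _ORIGIN + int(round(m / g) * g) * MINUTE

    s, e = perturb(iv.start), perturb(iv.end)
    if e <= s:
        e = s + g * MINUTE
    s = max(s, window.start)
    e = min(e, window.end)
    if e <= s:  # entry squeezed against the window edge
        s = max(window.start, e - g * MINUTE)
        e = s + g * MINUTE
    return Interval(s, e)


def _generate_participant(
    rng: np.random.Generator, cfg: GeneratorConfig, pid: str
) -> SyntheticParticipant:
    start = _ORIGIN + int(round(cfg.wake_start_hour * 60)) * MINUTE
    phases = _build_phases(rng, cfg, start)
    window = Interval(phases[0].interval.start, phases[-1].interval.end)
    n_min = window.duration_minutes

    counts = np.maximum(
        1, np.round(rng.lognormal(*cfg.counts_lognorm, size=n_min))
    ).astype(np.int64)
    placer = _Placer(n_min)

    def phase_slice(ph: Phase) -> tuple[int, int]:
        lo = int((ph.interval.start - window.start) // MINUTE)
        return lo, lo + ph.interval.duration_minutes

    # true removals (non-wear)
    n_removals = int(rng.poisson(cfg.removal_rate_per_24h * cfg.days_per_participant))
    truth_entries: list[NwtPeriod] = []
    waking = [p for p in phases if p.kind is PhaseKind.WAKING]
    sleeping = [p for p in phases if p.kind is PhaseKind.SLEEPING]
    for _ in range(n_removals):
        dur = _draw_minutes(rng, cfg.removal_duration_lognorm)
        dur = min(max(dur, cfg.removal_min_duration), cfg.removal_max_duration)
        pool = (
            waking
            if (rng.random() < cfg.removal_waking_fraction or not sleeping)
            else sleeping
        )
        placed = None
        for _ in range(5):  # try a few phases before giving up
            ph = pool[int(rng.integers(len(pool)))]
            lo, hi = phase_slice(ph)
            placed = placer.try_place(rng, lo, hi, dur)
            if placed is not None:
                break
        if placed is None:
            logger.debug("dropped removal of %d min for %s: no room", dur, pid)
            continue
        s, e = placed
        counts[s:e] = 0
        truth_entries.append(
            NwtPeriod(
                interval=Interval(window.start + s * MINUTE, window.start + e * MINUTE),
                source=Source.DIARY,
                reason=str(rng.choice(cfg.removal_reasons)),
            )
        )

    # wear-time zero runs (true wear, zero counts) — never reported in diaries
    for ph in phases:
        if ph.kind is PhaseKind.SLEEPING:
            n_runs = int(rng.poisson(cfg.sleep_motionless_runs_per_night))
            lognorm = cfg.sleep_motionless_lognorm
        else:
            n_runs = int(rng.poisson(cfg.waking_zero_runs_per_day))
            lognorm = cfg.waking_zero_lognorm
        lo, hi = phase_slice(ph)
        for _ in range(n_runs):
            dur = _draw_minutes(rng, lognorm)
            if cfg.max_wear_zero_run_min is not None:
                dur = min(dur, cfg.max_wear_zero_run_min)
            placed = placer.try_place(rng, lo, hi, dur)
            if placed is not None:
                counts[placed[0] : placed[1]] = 0

    truth_entries.sort(key=lambda e: e.interval.start)
    truth = DiaryRecord(pid, list(phases), truth_entries)
    reported_entries = [
        NwtPeriod(
            interval=_report_entry(rng, cfg, e.interval, window),
            source=Source.DIARY,
            reason=e.reason,
        )
        for e in truth_entries
    ]
    reported = DiaryRecord(pid, list(phases), reported_entries)
    series = EpochSeries(
        participant_id=pid,
        epoch_start=window.start,
        counts=counts,
        placement=cfg.placement if cfg.placement in ("hip", "wrist", "mixed") else None,
    )
    return SyntheticParticipant(series=series, truth=truth, reported=reported)


def _worked_example_participant() -> SyntheticParticipant:
    """Deterministic single-day layout of the printed validation example.

    The diary reports five waking non-wear periods of 30, 30, 115, 130 and 30
    minutes; the count stream holds three zero runs of 65 and 140 minutes
    (waking, inside the two long reported periods) and 75 minutes (sleeping).
    Counts intentionally follow the accelerometry layout rather than the diary
    — the two sources disagree by construction, as in real recordings.
    """
    day = _ORIGIN

    def at(hhmm: str, dur: int) -> Interval:
        h, m = map(int, hhmm.split(":"))
        s = day + (h * 60 + m) * MINUTE
        return Interval(s, s + dur * MINUTE)

    phases = [
        Phase(at("06:00", 16 * 60), PhaseKind.WAKING),
        Phase(at("22:00", 8 * 60), PhaseKind.SLEEPING),
    ]
    window = Interval(phases[0].interval.start, phases[1].interval.end)
    entries = [
        NwtPeriod(at("06:30", 30), Source.DIARY, reason="showering"),
        NwtPeriod(at("08:30", 30), Source.DIARY, reason="changing clothes"),
        NwtPeriod(at("10:00", 115), Source.DIARY, reason="water activities, sauna, or high contact sports"),
        NwtPeriod(at("13:00", 130), Source.DIARY, reason="water activities, sauna, or high contact sports"),
        NwtPeriod(at("18:00", 30), Source.DIARY, reason="personal hygiene"),
    ]
    zero_runs = [at("10:20", 65), at("12:55", 140), at("23:00", 75)]

    counts = np.full(window.duration_minutes, 500, dtype=np.int64)
    for iv in zero_runs:
        lo = int((iv.start - window.start) // MINUTE)
        counts[lo : lo + iv.duration_minutes] = 0

    diary = DiaryRecord("worked_example", phases, entries)
    series = EpochSeries("worked_example", window.start, counts, placement="hip")
    return SyntheticParticipant(series=series, truth=diary, reported=diary)


def generate(config: GeneratorConfig, seed: Optional[int] = None) -> list[SyntheticParticipant]:
    """Generate a cohort; reproducible for a fixed config (incl. its seed).

    ``seed`` overrides ``config.seed`` when given.  Deterministic layouts
    (``config.layout``) ignore the seed entirely.
    """
    if config.layout == "worked_example":
        return [_worked_example_participant()]
    if config.layout is not None:
        raise ValueError(f"unknown layout: {config.layout!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [
        _generate_participant(rng, config, f"P{i + 1:04d}")
        for i in range(config.n_participants)
    ]


def scenario_presets() -> dict[str, GeneratorConfig]:
    """Named generator configurations.

    * ``activE_like`` — hip-worn 24 h recording over two weeks; heavier tail
      of sleep-time motionless runs (hip devices register no wrist movement).
    * ``kora_like``   — one week, hip by day / wrist by night; lighter sleep
      motionless tail.
    * ``ideal``       — no reporting error, all removals well above 60 min,
      wear-time zero runs capped below any threshold: every validation metric
      should be perfect at T = 60.
    * ``worked_example`` — the deterministic printed single-day layout.
    """
    base = GeneratorConfig()
    return {
        "activE_like": replace(
            base,
            n_participants=47,
            days_per_participant=14,
            placement="hip",
            sleep_motionless_runs_per_night=3.0,
            sleep_motionless_lognorm=(math.log(50.0), 0.7),
        ),
        "kora_like": replace(
            base,
            n_participants=559,
            days_per_participant=7,
            placement="mixed",
            sleep_motionless_runs_per_night=3.0,
            sleep_motionless_lognorm=(math.log(25.0), 0.5),
        ),
        "ideal": replace(
            base,
            n_participants=47,
            days_per_participant=7,
            removal_duration_lognorm=(math.log(120.0), 0.3),
            removal_min_duration=75,
            removal_max_duration=300,
            removal_waking_fraction=0.7,
            sleep_motionless_lognorm=(math.log(20.0), 0.4),
            waking_zero_lognorm=(math.log(8.0), 0.5),
            max_wear_zero_run_min=45,
            diary_jitter_sd_min=0.0,
            diary_rounding_min=1,
        ),
        "worked_example": replace(base, n_participants=1, layout="worked_example"),
    }
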