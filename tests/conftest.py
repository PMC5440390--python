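"""Shared fixtures: a minute-offset interval builder and canned participants."""

import pandas as pd
import pytest

from nonwear.timeline import MINUTE, Interval
from nonwear.synthetic import generate, scenario_presets

T0 = pd.Timestamp("2017-05-01 00:00")


def iv(start_min: int, end_min: int) -> Interval:
    """Interval from minute offsets relative to a fixed origin."""
    return Interval(T0 + start_min * MINUTE, T0 + end_min * MINUTE)


def minute_set(interval: Interval) -> set[int]:
    """Brute-force per-minute membership enumeration of an interval."""
    lo = int((interval.start - T0) // MINUTE)
    hi = int((interval.end - T0) // MINUTE)
    return set(range(lo, hi))


@pytest.fixture
def mk():
    return iv


@pytest.fixture(scope="session")
def worked_example():
    """The deterministic printed single-day layout."""
    return generate(scenario_presets()["worked_example"])[0]


@pytest.fixture(scope="session")
def small_ideal_cohort():
    """A small error-free cohort for recovery checks in unit tests."""
    from dataclasses import replace

    cfg = replace(scenario_presets()["ideal"], n_participants=20, seed=42)
    return generate(cfg)
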