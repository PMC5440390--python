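"""Minute-by-minute overlap decomposition (thresholded and any-diary modes)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonwear.overlap import DiaryMode, decompose, run_approach2, run_approach3
from nonwear.matching import Stratum
from nonwear.timeline import minute_mask

from conftest import iv, minute_set

intervals_st = st.tuples(st.integers(0, 400), st.integers(1, 100)).map(
    lambda t: iv(t[0], t[0] + t[1])
)


def masks(diary_ivs, accel_ivs, window):
    return minute_mask(diary_ivs, window), minute_mask(accel_ivs, window)


def test_identical_sets_full_overlap():
    d, a = masks([iv(0, 60)], [iv(0, 60)], iv(0, 200))
    dec = decompose(d, a)
    assert (dec.pct_both, dec.pct_diary_only, dec.pct_accel_only) == (100.0, 0.0, 0.0)
    assert dec.potential_total == 60


def test_disjoint_sets():
    d, a = masks([iv(0, 60)], [iv(100, 140)], iv(0, 200))
    dec = decompose(d, a)
    assert dec.pct_both == 0.0
    assert dec.pct_diary_only == pytest.approx(60.0)
    assert dec.pct_accel_only == pytest.approx(40.0)


def test_empty_union_undefined():
    d, a = masks([], [], iv(0, 100))
    dec = decompose(d, a)
    assert dec.potential_total == 0
    assert dec.pct_both is None and dec.pct_diary_only is None


@given(
    diary=st.lists(intervals_st, max_size=6),
    accel=st.lists(intervals_st, max_size=6),
)
@settings(max_examples=150, deadline=None)
def test_decompose_matches_minute_set_enumeration(diary, accel):
    window = iv(0, 500)
    d_set = set().union(*(minute_set(i) for i in diary), set()) & minute_set(window)
    a_set = set().union(*(minute_set(i) for i in accel), set()) & minute_set(window)
    dec = decompose(*masks(diary, accel, window))
    assert dec.minutes_both == len(d_set & a_set)
    assert dec.minutes_diary_only == len(d_set - a_set)
    assert dec.minutes_accel_only == len(a_set - d_set)
    assert dec.potential_total == len(d_set | a_set)
    # conservation in minutes is exact, and percentages sum to 100
    if dec.potential_total:
        assert dec.pct_both + dec.pct_diary_only + dec.pct_accel_only == pytest.approx(100.0)
    # symmetry under swapping sources
    swapped = decompose(*masks(accel, diary, window))
    assert swapped.minutes_both == dec.minutes_both
    assert swapped.minutes_diary_only == dec.minutes_accel_only
    assert swapped.minutes_accel_only == dec.minutes_diary_only


def test_printed_example_approach2_layout(worked_example):
    dec = run_approach2(worked_example.reported, worked_example.series, 60)
    # diary {115,130}; accelerometry {65,140,75}; 65 inside the 115-entry,
    # 140-run covers the 130-entry with 10 extra minutes, 75 disjoint
    assert dec.n_diary_periods == 2 and dec.n_accel_periods == 3
    assert dec.minutes_both == 65 + 130
    assert dec.minutes_diary_only == (115 - 65)
    assert dec.minutes_accel_only == 10 + 75
    assert dec.potential_total == 245 + 85


def test_printed_example_approach3_counts(worked_example):
    dec = run_approach3(worked_example.reported, worked_example.series, 60)
    assert dec.n_diary_periods == 5
    assert dec.n_accel_periods == 3
    assert dec.diary_mode is DiaryMode.ANY
    # approach 3 diary minutes are a superset of approach 2's
    dec2 = run_approach2(worked_example.reported, worked_example.series, 60)
    assert dec.minutes_diary_total >= dec2.minutes_diary_total
    assert dec.pct_diary_only >= dec2.pct_diary_only


def test_threshold_above_everything_gives_empty_union(worked_example):
    dec = run_approach2(worked_example.reported, worked_example.series, 150)
    assert dec.potential_total == 0
    assert dec.pct_both is None


def test_no_accelerometry_nwt_means_all_diary_only(worked_example):
    dec = run_approach3(worked_example.reported, worked_example.series, 150)
    assert dec.pct_diary_only == 100.0
    assert dec.minutes_accel_only == 0


def test_accel_minutes_nonincreasing_in_threshold(worked_example):
    prev = None
    for t in (60, 90, 120, 150, 180):
        dec = run_approach3(worked_example.reported, worked_example.series, t)
        if prev is not None:
            assert dec.minutes_accel_total <= prev
            assert dec.minutes_accel_only <= prev
        prev = dec.minutes_accel_total


def test_stratum_restriction_minute_vs_period(worked_example):
    # minute-level: only sleeping minutes of the 75-min run remain
    dec_min = run_approach3(
        worked_example.reported, worked_example.series, 60, Stratum.SLEEPING
    )
    assert dec_min.minutes_accel_total == 75
    assert dec_min.minutes_diary_total == 0
    # waking stratum drops the sleeping run entirely
    dec_wak = run_approach2(
        worked_example.reported, worked_example.series, 60, Stratum.WAKING
    )
    assert dec_wak.minutes_accel_total == 65 + 140
    # period-level restriction keeps whole attributed periods
    dec_per = run_approach2(
        worked_example.reported,
        worked_example.series,
        60,
        Stratum.WAKING,
        stratum_restriction="period",
    )
    assert dec_per.minutes_accel_total == 65 + 140
    assert dec_per.n_accel_periods == 2
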