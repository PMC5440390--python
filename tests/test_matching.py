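"""Fourfold period classification and sensitivity/specificity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonwear.detection import EpochSeries, NwtPeriod, Source
from nonwear.diary import DiaryRecord
from nonwear.matching import (
    MatchTable,
    Stratum,
    classify,
    sens_spec,
    validate_participant,
)
from nonwear.timeline import Phase, PhaseKind

from conftest import T0, iv


def dp(a, b, t=60):
    return NwtPeriod(iv(a, b), Source.DIARY, threshold_minutes=t)


def ap(a, b, t=60):
    return NwtPeriod(iv(a, b), Source.ACCELEROMETRY, threshold_minutes=t)


def sub(a, b):
    return NwtPeriod(iv(a, b), Source.DIARY)


def test_printed_example_fourfold_counts(worked_example):
    """Two long reported periods matched >=50 %, one unmatched detected run,
    three untouched short entries -> a=2, b=1, c=0, d=3."""
    t = validate_participant(
        worked_example.reported, worked_example.series, 60, tn_units="entries"
    )
    assert (t.a_true_positive, t.b_false_positive) == (2, 1)
    assert (t.c_false_negative, t.d_true_negative) == (0, 3)
    assert t.not_assigned == 0
    res = sens_spec(t)
    assert res.sensitivity == pytest.approx(1.0)
    assert res.specificity == pytest.approx(0.75)


def test_hand_enumerated_scenario():
    # diary 115 min covered 65 min (>=50%), diary 130 min covered fully,
    # one stray accelerometry run, three short entries untouched
    diary = [dp(0, 115), dp(200, 330)]
    accel = [ap(25, 90), ap(200, 340), ap(500, 570)]
    subs = [sub(400, 430), sub(600, 630), sub(700, 730)]
    t = classify(diary, accel, subs)
    assert (t.a_true_positive, t.b_false_positive, t.c_false_negative,
            t.d_true_negative, t.not_assigned) == (2, 1, 0, 3, 0)


def test_perfect_agreement():
    periods = [(0, 100), (200, 330)]
    t = classify([dp(*p) for p in periods], [ap(*p) for p in periods])
    assert t.b_false_positive == t.c_false_negative == t.not_assigned == 0
    assert t.a_true_positive == 2


def test_empty_accelerometry_degenerate():
    diary = [dp(0, 100), dp(200, 330)]
    subs = [sub(400, 430)]
    t = classify(diary, [], subs)
    assert t.a_true_positive == 0 and t.b_false_positive == 0
    assert t.c_false_negative == 2
    assert t.d_true_negative == 1
    res = sens_spec(t)
    assert res.sensitivity == 0.0 and res.specificity == 1.0


def test_sub_50_percent_overlap_is_not_assigned():
    # 40 of 115 minutes covered: positive but < 50 % -> excluded
    t = classify([dp(0, 115)], [ap(75, 140)])
    assert t.not_assigned == 1
    assert t.a_true_positive == 0 and t.c_false_negative == 0
    res = sens_spec(t)
    assert res.sensitivity is None  # a + c == 0


def test_overlap_denominator_variants():
    # overlap 40; diary 115 (35%), accel 70 (57%)
    diary, accel = [dp(0, 115)], [ap(75, 145)]
    assert classify(diary, accel).not_assigned == 1
    t = classify(diary, accel, overlap_denominator="accelerometry")
    assert t.a_true_positive == 1
    t = classify(diary, accel, overlap_denominator="shorter")
    assert t.a_true_positive == 1


def test_greedy_assignment_prefers_larger_overlap_then_earlier():
    # one accelerometry run overlapping two diary periods
    diary = [dp(0, 100), dp(110, 220)]
    accel = [ap(40, 180)]
    t = classify(diary, accel)
    # larger overlap (70 min with the second) wins; first keeps positive
    # overlap but loses its only partner -> not assigned
    assert t.a_true_positive == 1
    assert t.not_assigned == 1
    # exact tie -> earlier diary period
    diary = [dp(0, 100), dp(120, 220)]
    accel = [ap(50, 170)]
    t = classify(diary, accel)
    assert t.a_true_positive == 1  # matched to the earlier (both 50/100 = 50 %)


def test_wear_blocks_as_true_negative_units():
    phases = [Phase(iv(0, 960), PhaseKind.WAKING), Phase(iv(960, 1440), PhaseKind.SLEEPING)]
    entries = [sub(100, 200)]
    d = DiaryRecord("p", phases, entries)
    counts = np.full(1440, 50)
    counts[100:200] = 0  # matches the reported removal
    s = EpochSeries("p", T0, counts)
    t = validate_participant(d, s, 60, tn_units="entries+wear_blocks")
    # wear blocks [0,100) and [200,1440) are clean -> d = 2
    assert t.d_true_negative == 2
    assert sens_spec(t).specificity == 1.0


def test_stratified_classification(worked_example):
    t_wak = validate_participant(
        worked_example.reported, worked_example.series, 60,
        Stratum.WAKING, tn_units="entries",
    )
    t_slp = validate_participant(
        worked_example.reported, worked_example.series, 60,
        Stratum.SLEEPING, tn_units="entries",
    )
    # both long reported periods and two runs are waking; the 75-min run sleeps
    assert (t_wak.a_true_positive, t_wak.b_false_positive) == (2, 0)
    assert (t_slp.a_true_positive, t_slp.b_false_positive) == (0, 1)
    assert t_wak.d_true_negative == 3 and t_slp.d_true_negative == 0


@pytest.mark.parametrize(
    "table, sens, spec",
    [
        (MatchTable(2, 1, 0, 3), 1.0, 0.75),
        (MatchTable(0, 0, 5, 0), 0.0, None),
        (MatchTable(0, 0, 0, 0), None, None),
        (MatchTable(3, 2, 1, 8), 0.75, 0.8),
    ],
)
def test_sens_spec_formulas(table, sens, spec):
    res = sens_spec(table)
    assert res.sensitivity == (pytest.approx(sens) if sens is not None else None)
    assert res.specificity == (pytest.approx(spec) if spec is not None else None)


@given(
    a=st.integers(0, 50), b=st.integers(0, 50),
    c=st.integers(0, 50), d=st.integers(0, 50),
)
@settings(max_examples=100, deadline=None)
def test_sens_spec_fuzzed_against_formula(a, b, c, d):
    res = sens_spec(MatchTable(a, b, c, d))
    assert res.sensitivity == (a / (a + c) if a + c else None)
    assert res.specificity == (d / (b + d) if b + d else None)
    for v in (res.sensitivity, res.specificity):
        if v is not None:
            assert 0.0 <= v <= 1.0


def test_match_table_rejects_negative_counts():
    with pytest.raises(ValueError):
        MatchTable(a_true_positive=-1)
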