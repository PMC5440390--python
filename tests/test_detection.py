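"""Zero-run detection: strict thresholds, oracle equivalence, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nonwear.detection import EpochSeries, detect_nwt, vector_magnitude

from conftest import T0


def series_from_runs(runs, pid="p1", sep=1):
    """Build a count series from alternating (value, minutes) zero/non-zero runs."""
    counts = []
    for dur_zero in runs:
        counts.extend([0] * dur_zero)
        counts.extend([100] * sep)
    counts.extend([100])
    return EpochSeries(pid, T0, np.array(counts))


def naive_zero_runs(counts):
    """Per-epoch scan oracle: maximal zero runs as (start, stop) indices."""
    runs, start = [], None
    for i, c in enumerate(counts):
        if c == 0 and start is None:
            start = i
        elif c != 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(counts)))
    return runs


def test_printed_example_run_lengths():
    s = series_from_runs([65, 140, 75])
    assert [p.duration_minutes for p in detect_nwt(s, 60)] == [65, 140, 75]
    assert [p.duration_minutes for p in detect_nwt(s, 90)] == [140]
    assert detect_nwt(s, 150) == []


def test_threshold_is_strict():
    s = series_from_runs([60])
    assert detect_nwt(s, 60) == []
    s = series_from_runs([61])
    assert len(detect_nwt(s, 60)) == 1


def test_single_nonzero_epoch_breaks_run():
    counts = np.array([0] * 40 + [5] + [0] * 40)
    s = EpochSeries("p", T0, counts)
    assert detect_nwt(s, 60) == []
    assert len(detect_nwt(s, 30)) == 2


def test_interruption_tolerance_bridges_runs():
    counts = np.array([100] + [0] * 40 + [5] + [0] * 40 + [100])
    s = EpochSeries("p", T0, counts)
    bridged = detect_nwt(s, 60, interruption_tolerance_epochs=1)
    assert [p.duration_minutes for p in bridged] == [81]
    assert detect_nwt(s, 60) == []  # off by default


def test_boundary_runs_are_flagged():
    counts = np.array([0] * 70 + [100] * 5 + [0] * 90)
    s = EpochSeries("p", T0, counts)
    periods = detect_nwt(s, 60)
    assert [p.at_gap for p in periods] == [True, True]
    inner = EpochSeries("p", T0, np.array([100] + [0] * 70 + [100]))
    assert [p.at_gap for p in detect_nwt(inner, 60)] == [False]


def test_input_validation():
    with pytest.raises(ValueError):
        EpochSeries("p", T0, np.array([1.5, 2.0]))
    with pytest.raises(ValueError):
        EpochSeries("p", T0, np.array([-1, 0]))
    with pytest.raises(ValueError):
        EpochSeries("p", T0, np.array([], dtype=int))
    s = EpochSeries("p", T0, np.array([0] * 100))
    with pytest.raises(ValueError):
        detect_nwt(s, 0)
    # non-integral epoch multiple of the threshold is rejected
    s90 = EpochSeries("p", T0, np.array([0] * 100), epoch_length=90)
    with pytest.raises(ValueError):
        detect_nwt(s90, 61)


@given(
    data=st.lists(
        st.tuples(st.booleans(), st.integers(1, 200)), min_size=1, max_size=30
    ),
    thresholds=st.sampled_from([60, 90, 120, 150, 180]),
)
@settings(max_examples=150, deadline=None)
def test_detection_matches_naive_scan(data, thresholds):
    counts = np.concatenate(
        [np.zeros(n, dtype=int) if z else np.full(n, 7) for z, n in data]
    )
    s = EpochSeries("p", T0, counts)
    expected = [
        (a, b) for a, b in naive_zero_runs(counts) if b - a > thresholds
    ]
    got = [
        (
            int((p.interval.start - T0).total_seconds() // 60),
            int((p.interval.end - T0).total_seconds() // 60),
        )
        for p in detect_nwt(s, thresholds)
    ]
    assert got == expected


@given(
    data=st.lists(
        st.tuples(st.booleans(), st.integers(1, 200)), min_size=1, max_size=30
    )
)
@settings(max_examples=60, deadline=None)
def test_monotone_in_threshold_and_disjoint(data):
    counts = np.concatenate(
        [np.zeros(n, dtype=int) if z else np.full(n, 7) for z, n in data]
    )
    s = EpochSeries("p", T0, counts)
    prev = None
    for t in (60, 90, 120, 150, 180):
        periods = detect_nwt(s, t)
        ivs = {(p.interval.start, p.interval.end) for p in periods}
        if prev is not None:
            assert ivs <= prev  # every period at T2 also found at T1 < T2
        prev = ivs
        for p, q in zip(periods, periods[1:]):
            assert p.interval.end <= q.interval.start  # ordered, disjoint
        # idempotence
        again = detect_nwt(s, t)
        assert {(p.interval.start, p.interval.end) for p in again} == ivs


@pytest.mark.parametrize(
    "xyz, expected", [((0, 0, 0), 0), ((3, 4, 0), 5), ((1, 0, 0), 1), ((2, 3, 6), 7)]
)
def test_vector_magnitude_examples(xyz, expected):
    assert vector_magnitude(*xyz) == expected


@given(st.tuples(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)))
@settings(max_examples=200, deadline=None)
def test_vector_magnitude_zero_iff_all_axes_zero(xyz):
    vm = vector_magnitude(*xyz)
    assert (vm == 0) == (xyz == (0, 0, 0))


def test_vector_magnitude_rejects_negative():
    with pytest.raises(ValueError):
        vector_magnitude(-1, 0, 0)
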