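"""Unit and property tests for the minute scorer, rescoring rules, sleep
period detection, night measures and the age-norm adjustment."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sleepvar import scoring
from sleepvar.scoring import (SLEEP, UNDEFINED, WAKE, EpochSeries, SleepPeriod,
                              adjust_for_age, compute_night_measures,
                              detect_sleep_period, rescore_labels, score_minute,
                              score_series)


def make_series(activity, offwrist=None, offset=-360):
    n = len(activity)
    return EpochSeries(
        participant_id="P", night_date=dt.date(2020, 1, 2),
        start_offset_min=offset, activity=np.asarray(activity),
        light=np.zeros(n),
        offwrist=np.zeros(n, dtype=bool) if offwrist is None else np.asarray(offwrist))


class TestScoreMinute:
    @pytest.mark.parametrize("window,s_expected,label", [
        ((0, 0, 0, 0, 0, 0, 0), 0.0, SLEEP),
        ((0, 0, 0, 0, 400, 0, 0), 3.036, WAKE),          # 0.0033 * 2.3 * 400
        ((100,) * 7, 2.1945, WAKE),                       # 0.0033 * 100 * 6.65
    ])
    def test_hand_arithmetic(self, window, s_expected, label):
        s, lab = score_minute(window)
        assert s == pytest.approx(s_expected, abs=1e-12)
        assert lab == label

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            score_minute([1, 2, 3])
        with pytest.raises(ValueError):
            score_minute([0, 0, 0, -1, 0, 0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 500), min_size=7, max_size=7))
    def test_linearity_and_threshold(self, window):
        s, lab = score_minute(window)
        s2, _ = score_minute([2 * w for w in window])
        assert s2 == pytest.approx(2 * s, rel=1e-12)
        assert (lab == SLEEP) == (s < 1.0)


class TestScoreSeries:
    def test_all_zero_boundaries_undefined(self):
        labels = score_series(make_series([0] * 60))
        assert np.all(labels[:4] == UNDEFINED)
        assert np.all(labels[-2:] == UNDEFINED)
        assert np.all(labels[4:58] == SLEEP)

    def test_constant_high_activity_is_wake(self):
        labels = score_series(make_series([400] * 30))
        assert np.all(labels[4:28] == WAKE)

    def test_offwrist_undefined(self):
        labels = score_series(make_series([0] * 20, offwrist=[True] * 20))
        assert np.all(labels == UNDEFINED)

    def test_too_short(self):
        with pytest.raises(ValueError):
            score_series(make_series([0] * 6))


class TestRescore:
    def test_all_sleep_unchanged(self):
        labels = np.full(50, SLEEP, dtype=np.int8)
        assert np.array_equal(rescore_labels(labels), labels)

    def test_disabled_identity(self):
        labels = np.array([WAKE] * 20 + [SLEEP] * 3 + [WAKE] * 20, dtype=np.int8)
        assert np.array_equal(rescore_labels(labels, enabled=False), labels)

    def test_isolated_short_bout_rescored(self):
        # 2 sleep minutes between two 15-minute wake bouts -> rescored wake
        labels = np.array([WAKE] * 15 + [SLEEP] * 2 + [WAKE] * 15, dtype=np.int8)
        assert np.all(rescore_labels(labels) == WAKE)

    @pytest.mark.parametrize("n_wake,n_rescored", [(3, 0), (4, 1), (10, 3), (15, 4)])
    def test_wake_tail_rules(self, n_wake, n_rescored):
        labels = np.array([n // 1 for n in [WAKE] * n_wake] + [SLEEP] * 30, dtype=np.int8)
        out = rescore_labels(labels)
        assert np.all(out[n_wake:n_wake + n_rescored] == WAKE)
        assert np.all(out[n_wake + n_rescored:] == SLEEP)

    def test_bout_rules_need_long_flanks(self):
        # 8-minute sleep bout: rescored only when flanked by >=20 min of wake
        short_flanks = np.array([WAKE] * 10 + [SLEEP] * 8 + [WAKE] * 10, dtype=np.int8)
        out = rescore_labels(short_flanks)
        assert np.any(out[10:18] == SLEEP)          # rule does not fire (flanks 10 < 20)
        long_flanks = np.array([WAKE] * 20 + [SLEEP] * 8 + [WAKE] * 20, dtype=np.int8)
        assert np.all(rescore_labels(long_flanks) == WAKE)

    def test_never_creates_sleep(self):
        rng = np.random.default_rng(5)
        labels = rng.choice([WAKE, SLEEP], size=300).astype(np.int8)
        out = rescore_labels(labels)
        assert not np.any((labels == WAKE) & (out == SLEEP))


class TestDetection:
    def test_all_sleep(self):
        labels = np.full(480, SLEEP)
        p = detect_sleep_period(labels)
        assert (p.start, p.end, p.valid) == (0, 479, True)

    def test_all_wake_invalid(self):
        p = detect_sleep_period(np.full(480, WAKE))
        assert not p.valid
        assert "no sleep run" in p.reason

    def test_toy_sequence_spans_first_to_last_run(self):
        labels = np.array([WAKE] * 30 + [SLEEP] * 300 + [WAKE] * 10
                          + [SLEEP] * 120 + [WAKE] * 30)
        p = detect_sleep_period(labels, min_run_minutes=20)
        assert (p.start, p.end) == (30, 459)

    def test_short_runs_ignored(self):
        labels = np.array([WAKE] * 30 + [SLEEP] * 10 + [WAKE] * 30)
        assert not detect_sleep_period(labels, min_run_minutes=20).valid

    def test_override_hook(self):
        labels = np.full(100, WAKE)
        p = detect_sleep_period(labels, override=(10, 80))
        assert (p.start, p.end, p.valid) == (10, 80, True)

    def test_light_contradiction(self):
        labels = np.full(100, SLEEP)
        bright = np.full(100, 500.0)
        p = detect_sleep_period(labels, light=bright, light_threshold=100)
        assert not p.valid


class TestNightMeasures:
    def test_pure_sleep(self):
        labels = np.array([SLEEP] * 4)
        rec = compute_night_measures(labels, SleepPeriod(0, 3, True), 0)
        assert rec.awakenings == 0
        assert rec.efficiency == 100.0

    def test_interleaved(self):
        labels = np.array([SLEEP, WAKE, SLEEP, WAKE, SLEEP])
        rec = compute_night_measures(labels, SleepPeriod(0, 4, True), 0)
        assert rec.awakenings == 2
        assert rec.efficiency == pytest.approx(60.0)

    def test_sleep_start_convention(self):
        # period starting at 22:30 against a midnight reference -> -90
        labels = np.full(600, SLEEP)
        rec = compute_night_measures(labels, SleepPeriod(0, 479, True), -90)
        assert rec.sleep_start == -90
        assert rec.duration == 480
        assert rec.sleep_end == 390

    def test_invalid_period(self):
        rec = compute_night_measures(np.full(10, WAKE),
                                     SleepPeriod(None, None, False, "nope"), 0)
        assert not rec.valid
        assert rec.invalid_reason == "nope"

    def test_undefined_inside_period_counts_as_wake(self):
        labels = np.array([SLEEP, UNDEFINED, SLEEP])
        rec = compute_night_measures(labels, SleepPeriod(0, 2, True), 0)
        assert rec.awakenings == 1
        assert rec.efficiency == pytest.approx(100 * 2 / 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([WAKE, SLEEP, UNDEFINED]), min_size=1, max_size=120))
    def test_efficiency_bounds(self, seg):
        labels = np.asarray(seg)
        rec = compute_night_measures(labels, SleepPeriod(0, len(seg) - 1, True), 0)
        assert 0 <= rec.efficiency <= 100
        assert (rec.efficiency == 100) == bool(np.all(labels == SLEEP))


class TestAgeAdjust:
    @pytest.mark.parametrize("value,measure,age,expected", [
        (600, "duration", 10, 0),
        (480, "duration", 30, 0),
        (500, "duration", 15, -40),
        (-210, "start", 8, 0),
        (-150, "start", 16, 0),
        (-90, "start", 40, 0),
    ])
    def test_norm_lookups(self, value, measure, age, expected):
        assert adjust_for_age(value, measure, age) == expected

    def test_age_below_range(self):
        with pytest.raises(ValueError):
            adjust_for_age(480, "duration", 4)

    def test_unknown_measure(self):
        with pytest.raises(ValueError):
            adjust_for_age(480, "latency", 20)


class TestRecovery:
    def test_detected_period_close_to_truth(self, default_arch):
        """Observability chain: scoring generated nights recovers the true
        interval within +/-15 min at both ends in >=90% of nights."""
        from sleepvar import cohort
        hits = 0
        n = 120
        for i in range(n):
            series, truth = cohort.generate_night(default_arch, dt.date(2020, 1, 1), seed=i)
            rec = scoring.score_night(series)
            assert rec.valid
            if (abs(rec.sleep_start - truth.true_start) <= 15
                    and abs(rec.sleep_end - truth.true_end) <= 15):
                hits += 1
        assert hits / n >= 0.90
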