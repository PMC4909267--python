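"""Unit and property tests for the event detectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apnealab as al
from apnealab.core import Channel
from apnealab.detect import BreathSeries, detect_r_peaks, instantaneous_hr
from oracles import assert_runs_equal, brute_pauses, brute_threshold_runs


# ---------------------------------------------------------------------------
# breaths
# ---------------------------------------------------------------------------

class TestDetectBreaths:
    def test_pure_sinusoid_has_one_breath_per_cycle(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        ch = Channel(np.sin(2 * np.pi * 1.0 * t), fs)
        breaths = al.detect_breaths(ch)
        assert abs(len(breaths) - 60) <= 1
        spacing = np.diff(breaths.onsets)
        assert np.all(np.abs(spacing - 1.0) <= 0.02 + 1e-9)

    def test_no_onsets_inside_silent_gap(self):
        # a 13-s central silence: no breaths may be scored within it
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        x = np.sin(2 * np.pi * 1.0 * t)
        x[(t >= 50) & (t < 63)] = 0.0
        breaths = al.detect_breaths(Channel(x, fs))
        inside = (breaths.onsets > 50.5) & (breaths.onsets < 62.5)
        assert not inside.any()

    def test_onsets_match_generator_breath_times(self, quiet_params, short_schedule):
        rec, truth = al.generate_recording(quiet_params, short_schedule)
        breaths = al.detect_breaths(rec["resp"])
        # same number of breaths, each within 0.2 s of a generated breath
        assert len(breaths) == truth.breath_times.size
        assert np.max(np.abs(breaths.onsets - truth.breath_times)) <= 0.2

    def test_all_invalid_channel_is_an_error(self):
        ch = Channel(np.zeros(1000), 50.0, np.zeros(1000, dtype=bool))
        with pytest.raises(ValueError):
            al.detect_breaths(ch)


# ---------------------------------------------------------------------------
# pauses
# ---------------------------------------------------------------------------

def _regular_onsets_with_gaps(period, total, gaps):
    """Breath-onset grid with silent windows (start, dur) removed."""
    onsets = np.arange(period / 2, total, period)
    keep = np.ones(onsets.size, dtype=bool)
    for a, d in gaps:
        keep &= ~((onsets >= a) & (onsets < a + d))
    return onsets[keep]


class TestDetectPauses:
    def test_regular_breathing_yields_no_pauses(self):
        b = BreathSeries(np.arange(0, 60, 1.1), np.ones(55))
        assert len(al.detect_pauses(b)) == 0

    @pytest.mark.parametrize(
        "gap,expected_type",
        [(4.0, "pause_short"), (13.0, "pause_long")],
    )
    def test_single_gap_classified_against_oracle(self, gap, expected_type):
        onsets = _regular_onsets_with_gaps(1.0, 120.0, [(50.0, gap)])
        events = al.detect_pauses(BreathSeries(onsets, np.ones(onsets.size)))
        oracle = brute_pauses(onsets)
        assert len(events) == len(oracle) == 1
        e, (o_on, o_dur, o_kind) = events.events[0], oracle[0]
        assert e.type == expected_type
        assert {"short": "pause_short", "long": "pause_long"}[o_kind] == e.type
        assert e.onset == pytest.approx(o_on)
        assert e.duration == pytest.approx(o_dur)

    def test_boundary_five_seconds_is_short(self):
        # a silent interval of exactly period + 5.0 s -> pause of 5.0 s -> short
        onsets = np.concatenate([np.arange(0, 30, 1.0), np.arange(35.0, 65.0, 1.0)])
        events = al.detect_pauses(BreathSeries(onsets, np.ones(onsets.size)))
        assert len(events) == 1
        assert events.events[0].type == "pause_short"
        assert events.events[0].duration == pytest.approx(5.0)

    def test_fewer_than_two_breaths_gives_empty_list(self):
        assert len(al.detect_pauses(BreathSeries(np.array([1.0]), np.array([1.0])))) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(20, 280), st.floats(3.2, 20)), max_size=3))
    def test_random_gap_sets_match_oracle(self, gaps):
        # keep gaps separated so both definitions see distinct silent intervals
        gaps = sorted(gaps)
        gaps = [g for i, g in enumerate(gaps) if i == 0 or g[0] - gaps[i - 1][0] > 60]
        onsets = _regular_onsets_with_gaps(1.1, 400.0, gaps)
        events = al.detect_pauses(BreathSeries(onsets, np.ones(onsets.size)))
        oracle = brute_pauses(onsets)
        assert len(events) == len(oracle)
        for e, (o_on, o_dur, _) in zip(events, oracle):
            assert e.onset == pytest.approx(o_on)
            assert e.duration == pytest.approx(o_dur)


# ---------------------------------------------------------------------------
# oximeter averaging
# ---------------------------------------------------------------------------

class TestSmoothSpo2:
    def test_constant_signal_unchanged(self):
        ch = Channel(np.full(100, 96.0), 1.0)
        out = al.smooth_spo2(ch, window=8.0)
        assert np.allclose(out.data, 96.0)

    @pytest.mark.parametrize("rate", [1.0, 5.0, 25.0])
    def test_step_response_ramps_linearly_over_window(self, rate):
        # step 98 -> 88: the average first equals 88 exactly 8 s after the
        # last 98-sample, ramping linearly in between (mean of a step over a
        # trailing boxcar)
        n = int(30 * rate)
        i0 = int(10 * rate)  # first 88-valued sample
        x = np.full(n, 98.0)
        x[i0:] = 88.0
        out = al.smooth_spo2(Channel(x, rate), window=8.0)
        w = int(round(8 * rate))
        reached = np.flatnonzero(out.data == 88.0)
        t_last98 = (i0 - 1) / rate
        assert reached[0] / rate == pytest.approx(t_last98 + 8.0)
        # closed form on the ramp: mean of k samples at 88 and w-k at 98
        for k in range(1, w):
            expected = (k * 88.0 + (w - k) * 98.0) / w
            assert out.data[i0 + k - 1] == pytest.approx(expected)

    def test_single_sample_window_is_identity(self, rng):
        x = 90 + rng.normal(0, 2, 50)
        ch = Channel(x, 1.0)
        out = al.smooth_spo2(ch, window=1.0)
        assert np.allclose(out.data, x)

    def test_invalid_samples_excluded_from_average(self):
        x = np.full(20, 96.0)
        x[5] = 0.0  # artifact
        valid = np.ones(20, dtype=bool)
        valid[5] = False
        out = al.smooth_spo2(Channel(x, 1.0, valid), window=4.0)
        assert np.allclose(out.data[out.valid], 96.0)


# ---------------------------------------------------------------------------
# threshold detectors (desaturation / bradycardia)
# ---------------------------------------------------------------------------

class TestThresholdDetectors:
    def test_constant_normal_signals_give_no_events(self):
        assert len(al.detect_desaturations(Channel(np.full(600, 96.0), 1.0))) == 0
        assert len(al.detect_bradycardia(Channel(np.full(600, 150.0), 1.0))) == 0

    def test_six_second_dip_to_89_only_crosses_90(self):
        x = np.full(60, 95.0)
        x[20:26] = 89.0
        events = al.detect_desaturations(Channel(x, 1.0))
        assert len(events.sublist("desat", "<90")) == 1
        assert events.sublist("desat", "<90").events[0].duration == pytest.approx(6.0)
        assert len(events.sublist("desat", "<88")) == 0
        assert len(events.sublist("desat", "<85")) == 0

    def test_deep_bradycardia_scored_at_both_thresholds(self):
        x = np.full(120, 150.0)
        x[50:60] = 95.0
        events = al.detect_bradycardia(Channel(x, 1.0))
        for thr in ("<110", "<100"):
            sub = events.sublist("brady", thr)
            assert len(sub) == 1
            assert sub.events[0].duration == pytest.approx(10.0)

    def test_sample_equal_to_threshold_ends_episode(self):
        # strict inequality: 90.0 itself is not "below 90"
        x = np.array([95, 89, 89, 90, 89, 89, 89, 89, 89, 95], dtype=float)
        events = al.detect_desaturations(Channel(x, 1.0), thresholds=(90.0,), min_dur=5.0)
        assert len(events) == 1
        assert events.events[0].onset == pytest.approx(4.0)
        assert events.events[0].duration == pytest.approx(5.0)

    def test_gap_merge_joins_brief_recoveries(self):
        x = np.full(40, 95.0)
        x[5:10] = 88.0
        x[11:16] = 88.0
        ch = Channel(x, 1.0)
        split = al.detect_desaturations(ch, thresholds=(90.0,), min_dur=5.0)
        merged = al.detect_desaturations(ch, thresholds=(90.0,), min_dur=5.0, gap_merge=2.0)
        assert len(split) == 2
        assert len(merged) == 1
        assert merged.events[0].duration == pytest.approx(11.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(20, 3000))
    def test_oracle_equivalence_random_signals(self, seed, n):
        # vectorised detector == brute-force boolean run scanner, exactly
        r = np.random.default_rng(seed)
        data = r.normal(92, 5, n).round(1)
        valid = r.random(n) > 0.05
        ch = Channel(np.where(valid, data, np.nan), 2.0, valid)
        events = al.detect_desaturations(ch, thresholds=(90.0, 88.0), min_dur=5.0)
        for thr in (90.0, 88.0):
            got = [
                (e.onset, e.duration) for e in events.sublist("desat", f"<{thr:g}")
            ]
            assert_runs_equal(got, brute_threshold_runs(data, valid, 2.0, thr, 5.0))

    def test_duration_monotonicity_across_nested_thresholds(self, rng):
        data = rng.normal(91, 4, 5000)
        ch = Channel(data, 1.0)
        events = al.detect_desaturations(ch, min_dur=5.0)
        totals = [
            sum(e.duration for e in events.sublist("desat", lab))
            for lab in ("<85", "<88", "<90")
        ]
        assert totals[0] <= totals[1] <= totals[2]

    def test_threshold_subset_is_idempotent(self, rng):
        data = rng.normal(91, 4, 2000)
        ch = Channel(data, 1.0)
        single = al.detect_desaturations(ch, thresholds=(90.0,))
        full = al.detect_desaturations(ch, thresholds=(90.0, 88.0, 85.0))
        assert single.events == full.sublist("desat", "<90").events

    def test_translation_invariance(self, rng):
        data = rng.normal(91, 4, 1000)
        ch = Channel(data, 1.0)
        base = al.detect_desaturations(ch)
        shifted = al.detect_desaturations(ch, start_time=3600.0)
        assert len(base) == len(shifted)
        for a, b in zip(base, shifted):
            assert b.onset == pytest.approx(a.onset + 3600.0)
            assert b.duration == pytest.approx(a.duration)


# ---------------------------------------------------------------------------
# heart rate from ECG
# ---------------------------------------------------------------------------

class TestHeartRate:
    def test_constant_rr_gives_constant_150_bpm(self):
        fs = 250.0
        ecg = np.zeros(int(60 * fs))
        ecg[(np.arange(0.2, 60, 0.4) * fs).astype(int)] = 1.0
        hr = al.compute_heart_rate(Channel(ecg, fs))
        assert np.allclose(hr.data[hr.valid], 150.0)

    def test_instantaneous_hr_is_60_over_rr(self):
        t, hr, ok = instantaneous_hr(np.array([0.0, 0.4, 0.8, 1.3]))
        assert hr == pytest.approx([150.0, 150.0, 120.0])
        assert ok.all()

    def test_implausible_rr_flagged_invalid(self):
        t, hr, ok = instantaneous_hr(np.array([0.0, 0.1, 0.5, 4.5]))
        assert list(ok) == [False, True, False]

    def test_refractory_period_rejects_double_counting(self):
        fs = 250.0
        ecg = np.zeros(int(30 * fs))
        beats = np.arange(0.2, 30, 0.5)
        ecg[(beats * fs).astype(int)] = 1.0
        ecg[(beats * fs).astype(int) + 3] = 0.6  # spurious afterpotential 12 ms later
        r = detect_r_peaks(Channel(ecg, fs))
        assert r.size == beats.size

    def test_synthetic_ecg_recovers_hr_channel(self, quiet_params, short_schedule):
        rec, _ = al.generate_recording(quiet_params, short_schedule)
        hr = al.compute_heart_rate(rec["ecg"])
        step = int(quiet_params.hr_rate)
        true_hr = rec["hr"].data[::step][: hr.n]
        err = np.abs(hr.data[hr.valid] - true_hr[hr.valid])
        assert np.median(err) < 2.0
        # baseline of the synthetic population lies in the expected band
        assert 150 <= np.median(hr.data[hr.valid]) <= 165
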