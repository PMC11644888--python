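"""Derivative thresholding, event emission, features and windowing."""

import numpy as np
import pytest

import capblink as cb

class TestDifferentiate:
    def test_constant_series_gives_zero(self):
        t = np.arange(0, 5, 0.01)
        d = cb.differentiate(cb.FrequencySeries(t, np.full_like(t, 3.0)), rescale=False)
        assert np.allclose(d.values, 0.0, atol=1e-9)

    def test_ramp_gives_constant_slope(self):
        t = np.arange(0, 5, 0.01)
        a = -4.2
        d = cb.differentiate(cb.FrequencySeries(t, a * t), rescale=False)
        assert np.allclose(d.values[1:-1], a, rtol=1e-9)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(0, 10, 0.01)
        x = np.sin(2 * np.pi * 3.0 * t)
        d = cb.differentiate(cb.FrequencySeries(t, x), rescale=False)
        expected = 6.0 * np.pi * np.cos(2 * np.pi * 3.0 * t)
        core = slice(1, -1)
        rms_err = np.sqrt(np.mean((d.values[core] - expected[core]) ** 2))
        rms_ref = np.sqrt(np.mean(expected[core] ** 2))
        assert rms_err / rms_ref < 0.01

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            cb.differentiate(cb.FrequencySeries(np.array([0.0, 1.0]), np.array([1.0, 2.0])))

    def test_rescaled_units_make_noise_scale_one(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60, 0.01)
        d = cb.differentiate(cb.FrequencySeries(t, rng.normal(0, 5.0, t.size)))
        # robust scale of the rescaled derivative should be ~1 regardless of gain
        mad = np.median(np.abs(d.values - np.median(d.values)))
        assert 0.8 < 1.4826 * mad < 1.2


class TestDetect:
    def test_flat_derivative_gives_no_events(self):
        t = np.arange(0, 10, 0.01)
        deriv = cb.FrequencySeries(t, np.zeros_like(t))
        assert cb.detect(deriv) == []

    def test_subthreshold_bump_rejected_by_confidence(self):
        """Peak at half the threshold cannot reach confidence 1."""
        t = np.arange(0, 10, 0.01)
        d = np.zeros_like(t)
        d[400:405] = -2.0  # theta/2 for 0.05 s (c_dur = 1)
        events = cb.detect(cb.FrequencySeries(t, d))
        assert events == []

    def test_bench_scenario_recovers_all_scheduled_blinks(self, bench_recording, run_detection_pipeline):
        series, labels = bench_recording
        events = run_detection_pipeline(series)
        assert len(events) == len(labels)
        for got, true in zip(events, labels.events):
            assert abs(got.onset - true.onset) <= 0.1
            assert got.confidence > 1.0

    def test_detection_invariant_to_offset_and_subband_drift(self, run_detection_pipeline):
        """Constant offsets and sub-passband drift never change the count."""
        drop = 4777.0
        for seed in range(20):
            sched = cb.random_schedule(40.0, n_events=6, seed=seed)
            noise = cb.NoiseSpec(white_sd=0.005 * drop, seed=seed)
            base, _ = cb.generate_recording(sched, noise=noise, fs=100.0)
            n_base = len(run_detection_pipeline(base))
            drift = 5000.0 * np.sin(2 * np.pi * base.times / 25.0) + 1e4
            shifted = cb.FrequencySeries(base.times, base.values + drift)
            assert len(run_detection_pipeline(shifted)) == n_base

    def test_recall_degrades_monotonically_with_noise(self, run_detection_pipeline):
        """Recall is non-increasing along a rising white-noise grid (one
        sampling inversion allowed)."""
        drop = 4777.0
        recalls = []
        for frac in (0.01, 0.05, 0.2, 0.5, 1.0):
            hits = total = 0
            for seed in range(8):
                sched = cb.random_schedule(40.0, n_events=6, seed=seed)
                noise = cb.NoiseSpec(white_sd=frac * drop, seed=seed)
                series, _ = cb.generate_recording(sched, noise=noise, fs=100.0)
                events = run_detection_pipeline(series)
                for ev in sched.events:
                    total += 1
                    if any(abs(e.onset - ev.onset) < 0.3 for e in events):
                        hits += 1
            recalls.append(hits / total)
        inversions = sum(1 for a, b in zip(recalls, recalls[1:]) if b > a + 1e-12)
        assert recalls[0] == 1.0
        assert inversions <= 1
        assert recalls[-1] < recalls[0]


class TestExtractFeatures:
    def test_empty_window_degenerate_policy(self):
        feats = cb.extract_features([], window=(0.0, 40.0))
        assert (feats.closing, feats.opening, feats.idle, feats.count) == (0.0, 0.0, 40.0, 0)

    def test_two_event_idle_time_arithmetic(self):
        events = [
            cb.BlinkEvent(onset=5.0, closing=0.15, opening=0.25, confidence=2.0),
            cb.BlinkEvent(onset=15.0, closing=0.15, opening=0.25, confidence=2.0),
        ]
        feats = cb.extract_features(events, window=(0.0, 40.0))
        assert feats.idle == pytest.approx(15.0 - (5.0 + 0.4))
        assert feats.closing == pytest.approx(0.15)
        assert feats.count == 2

    def test_single_scheduled_blink_recovered_to_one_sample(self):
        sched = cb.BlinkSchedule(
            events=(cb.BlinkInterval(onset=5.0, closing=0.15, hold=0.08, opening=0.25),),
            duration=40.0,
        )
        series, _ = cb.generate_recording(sched, fs=100.0)
        events = cb.detect(cb.differentiate(series))
        feats = cb.extract_features(events, window=(0.0, 40.0))
        assert feats.count == 1
        assert abs(feats.closing - 0.15) <= 0.01 + 1e-9
        assert abs(feats.opening - 0.25) <= 0.01 + 1e-9

    def test_events_outside_window_ignored(self):
        events = [cb.BlinkEvent(onset=45.0, closing=0.1, opening=0.2, confidence=2.0)]
        feats = cb.extract_features(events, window=(0.0, 40.0))
        assert feats.count == 0


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "length_s,expected",
        [(260.0, 111), (40.0, 1), (39.0, 0)],
    )
    def test_window_counts(self, length_s, expected):
        n = int(round(length_s * 100))
        t = np.arange(n) / 100.0
        series = cb.FrequencySeries(t, np.zeros(n))
        assert len(cb.sliding_windows(series, 40.0, 2.0)) == expected

    def test_starts_are_multiples_of_step(self):
        t = np.arange(6000) / 100.0
        wins = cb.sliding_windows(cb.FrequencySeries(t, np.zeros(6000)), 40.0, 2.0)
        starts = [w[0] for w in wins]
        assert starts == [2.0 * k for k in range(len(wins))]

    def test_invalid_step_rejected(self):
        t = np.arange(100) / 100.0
        with pytest.raises(ValueError):
            cb.sliding_windows(cb.FrequencySeries(t, np.zeros(100)), 40.0, 0.0)
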