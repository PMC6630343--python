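import numpy as np
import pytest

from drivestress.io_signals import SignalTrace, StageAnnotation
from drivestress.rpeak import (
    AgeWindows,
    NormalizedTrace,
    RPeakSeries,
    age_windows,
    detect_rpeaks,
    normalize_ecg,
    rr_from_peaks,
    stage_rr_summary,
)
from drivestress.synth import GeneratorParams, rr_to_ecg

from conftest import beat_train


def ecg_trace(values, fs=256.0, t0=0.0):
    return SignalTrace(t0=t0, fs=fs, values=np.asarray(values, float), kind="ecg")


class TestNormalize:
    def test_constant_trace_maps_to_zero(self):
        trace = ecg_trace(np.full(1024, 3.7))
        norm = normalize_ecg(trace, 2.0)
        np.testing.assert_array_equal(norm.values, 0.0)

    def test_matches_hand_computed_zscore(self):
        # one 8-sample window at 4 Hz; sample SD (n-1 denominator) convention
        vals = [1.0, 3.0, 1.0, 3.0, 1.0, 3.0, 1.0, 3.0]
        mean = 2.0
        sd = (sum((v - mean) ** 2 for v in vals) / 7) ** 0.5  # 1.0690...
        expected = [(v - mean) / sd for v in vals]
        norm = normalize_ecg(ecg_trace(vals, fs=4.0), 2.0)
        np.testing.assert_allclose(norm.values, expected, atol=1e-12)

    def test_each_window_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        norm = normalize_ecg(ecg_trace(rng.normal(size=2048)), 2.0)
        w = 512
        for i in range(4):
            block = norm.values[i * w : (i + 1) * w]
            assert abs(block.mean()) < 1e-9
            assert abs(block.std(ddof=1) - 1) < 1e-9

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize_ecg(ecg_trace(np.zeros(100)), 2.0)


class TestAgeWindows:
    def test_closed_form_values(self):
        w20 = age_windows(20)
        assert w20.twrd_s == pytest.approx(60 / (0.77 * 200))
        assert w20.refractory_s == pytest.approx(0.300)
        w70 = age_windows(70)
        assert w70.twrd_s == pytest.approx(60 / (0.77 * 150))
        assert w70.refractory_s == pytest.approx(0.400)

    def test_search_window_grows_with_age(self):
        tw = [age_windows(a).twrd_s for a in range(16, 101)]
        assert np.all(np.diff(tw) > 0)

    @pytest.mark.parametrize("age", [15, 101])
    def test_age_out_of_range(self, age):
        with pytest.raises(ValueError):
            age_windows(age)


class TestDetect:
    def test_single_bump_detected_at_apex(self):
        fs = 256.0
        t = np.arange(int(4 * fs)) / fs
        vals = 4.0 * np.exp(-0.5 * ((t - 2.0) / 0.008) ** 2)
        norm = NormalizedTrace(t0=0.0, fs=fs, values=vals, norm_window_s=2.0)
        peaks = detect_rpeaks(norm, age_windows(30))
        assert peaks.n == 1
        assert peaks.peak_times[0] == pytest.approx(2.0, abs=1e-9)

    def test_refractory_removes_duplicate_pick(self):
        # two candidates 150 ms apart land in adjacent search frames; they
        # cannot be two beats (refractory 300 ms), so only the true apex
        # (the larger, earlier one) survives
        fs = 1000.0
        vals = np.zeros(int(fs))
        vals[350] = 5.0
        vals[500] = 4.0  # 150 ms later, next frame
        norm = NormalizedTrace(t0=0.0, fs=fs, values=vals, norm_window_s=1.0)
        windows = AgeWindows(twrd_s=0.4, refractory_s=0.3)
        peaks = detect_rpeaks(norm, windows, stage_stats={"all": (0.0, 1.0)})
        assert peaks.n == 1
        assert peaks.peak_times[0] == pytest.approx(0.35)

    def test_noise_free_train_recovered_exactly(self):
        params = GeneratorParams(group="young", seed=0, noise_sd_mv=0.0, wander_sd_mv=0.0)
        beats = beat_train(60.0, 120.0)
        snapped = np.round(beats * params.fs_ecg) / params.fs_ecg
        trace = _trace_120s(snapped, params)
        norm = normalize_ecg(trace, 2.0)
        peaks = detect_rpeaks(norm, age_windows(20))
        np.testing.assert_array_equal(peaks.peak_times, snapped)

    def test_no_two_peaks_within_refractory(self, elderly_session):
        ecg, _, _, params = elderly_session
        norm = normalize_ecg(ecg, 2.0)
        windows = age_windows(65)
        peaks = detect_rpeaks(norm, windows)
        assert np.all(np.diff(np.sort(peaks.peak_times)) >= windows.refractory_s - 1e-12)

    def test_recall_degrades_monotonically_with_noise(self):
        recalls = []
        beats = beat_train(60.0, 120.0)
        for noise in (0.02, 0.3, 0.8):
            params = GeneratorParams(
                group="young", seed=5, noise_sd_mv=noise, wander_sd_mv=0.0
            )
            snapped = np.round(beats * params.fs_ecg) / params.fs_ecg
            trace = _trace_120s(snapped, params)
            peaks = detect_rpeaks(normalize_ecg(trace, 2.0), age_windows(20))
            hits = sum(np.min(np.abs(peaks.peak_times - b)) < 0.04 for b in snapped)
            recalls.append(hits / snapped.size)
        assert recalls[0] >= recalls[1] >= recalls[2]

    def test_weak_qrs_has_full_noise_free_recall(self):
        # normalization makes detection amplitude-invariant: a 40% QRS
        # (elderly morphology) loses nothing without noise
        beats = beat_train(60.0, 120.0)
        times = {}
        for amp in (1.0, 0.4):
            params = GeneratorParams(
                group="young", seed=0, noise_sd_mv=0.0, wander_sd_mv=0.0, qrs_amplitude_mv=amp
            )
            snapped = np.round(beats * params.fs_ecg) / params.fs_ecg
            trace = _trace_120s(snapped, params)
            peaks = detect_rpeaks(normalize_ecg(trace, 2.0), age_windows(20))
            times[amp] = peaks.peak_times
            np.testing.assert_array_equal(peaks.peak_times, snapped)
        np.testing.assert_array_equal(times[1.0], times[0.4])


def _trace_120s(beat_times, params):
    """Render beats over a 120-s span (short stages for detector tests)."""
    stages = StageAnnotation(before=(0, 5), driving=(5, 115), after=(115, 120), discard_head=0.0)
    return rr_to_ecg(beat_times, params.with_overrides(stages=stages))


class TestRRSeries:
    def test_successive_differences_stamped_at_later_peak(self):
        peaks = RPeakSeries(
            peak_times=np.array([1.0, 1.8, 2.6]),
            peak_values=np.ones(3),
            stage=np.array(["driving"] * 3, dtype=object),
        )
        rr = rr_from_peaks(peaks)
        np.testing.assert_allclose(rr.rr_ms, [800.0, 800.0])
        np.testing.assert_allclose(rr.rr_times, [1.8, 2.6])

    def test_no_interval_spans_stage_boundary(self):
        peaks = RPeakSeries(
            peak_times=np.array([59.2, 59.9, 60.4, 61.1]),
            peak_values=np.ones(4),
            stage=np.array(["before", "before", "driving", "driving"], dtype=object),
        )
        rr = rr_from_peaks(peaks)
        assert rr.n == 2  # one per stage; none across the 60-s boundary
        assert set(rr.stage) == {"before", "driving"}

    def test_summary_mean_and_sd(self):
        peaks = RPeakSeries(
            peak_times=np.array([1.0, 1.8, 2.6]),
            peak_values=np.ones(3),
            stage=np.array(["driving"] * 3, dtype=object),
        )
        summ = stage_rr_summary(rr_from_peaks(peaks))
        assert summ["driving"].mean == pytest.approx(800.0)
        assert summ["driving"].sd == 0.0

    def test_single_interval_flagged_degenerate(self):
        peaks = RPeakSeries(
            peak_times=np.array([1.0, 1.7]),
            peak_values=np.ones(2),
            stage=np.array(["before"] * 2, dtype=object),
        )
        summ = stage_rr_summary(rr_from_peaks(peaks))
        assert summ["before"].mean == pytest.approx(700.0)
        assert summ["before"].sd == 0.0
        assert summ["before"].sd_degenerate


def test_generator_baseline_recovered_through_detector(elderly_report):
    """Driving-stage mean RR lands near the planted elderly baseline."""
    summ = elderly_report.rr_summary
    assert summ["driving"].mean == pytest.approx(752.87, abs=25.0)
    assert summ["before"].mean == pytest.approx(812.29, abs=25.0)
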