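"""Beat segmentation, fiducial detection and the 11-feature vector."""

import dataclasses

import numpy as np
import pytest

from pulsebp.features import (
    Beat,
    DegenerateBeatError,
    FEATURE_NAMES,
    FiducialPoints,
    RecordRejectedError,
    compute_features,
    detect_fiducials,
    featurize_recording,
    segment_beats,
)
from pulsebp.simulate import (
    SimulationConfig,
    beat_params_from_bp,
    generate_beat_template,
    generate_recording,
)

FS = 250.0


def _periodic_train(params, n_beats):
    y, truth = generate_beat_template(params, FS)
    return np.tile(y, n_beats), truth


class TestSegmentation:
    def test_beat_count_for_30s_75bpm_train(self):
        params = beat_params_from_bp(118, 70, hr_bpm=75.0)
        n = int(np.ceil(30.0 / params.beat_period_s))
        signal = _periodic_train(params, n)[0][: int(30 * FS)]
        beats = segment_beats(signal, FS)
        # 37 full periods fit; boundary partials are discarded
        assert abs(len(beats) - 36) <= 1

    def test_constant_signal_yields_no_beats(self):
        assert segment_beats(np.ones(5000), FS) == []

    def test_single_period_between_partials_yields_one_beat(self):
        params = beat_params_from_bp(118, 70, hr_bpm=75.0)
        y, _ = generate_beat_template(params, FS)
        half = len(y) // 2
        signal = np.concatenate([y[half:], y, y[:half]])
        beats = segment_beats(signal, FS)
        assert len(beats) == 1

    def test_beats_have_interior_maxima_and_plausible_lengths(
            self, noisy_recording):
        from pulsebp.emd import denoise
        rec, _ = noisy_recording
        den = denoise(rec.channels[1], FS)
        beats = segment_beats(den, FS)
        assert len(beats) >= 5
        for b in beats:
            peak = int(np.argmax(b.samples))
            assert 0 < peak < len(b.samples) - 1
            assert 0.25 * FS <= len(b.samples) <= FS * 60 / 40


class TestFiducials:
    def test_template_beat_landmarks_within_one_sample(self):
        params = dataclasses.replace(
            beat_params_from_bp(118, 70, hr_bpm=75.0),
            systolic_time_s=0.15, dicrotic_time_s=0.40,
            notch_time_s=0.28, systolic_amp=1.0, dicrotic_amp=0.4,
            runoff_amp=0.35)
        signal, truth = _periodic_train(params, 5)
        beats = segment_beats(signal, FS)
        assert len(beats) >= 2
        f = detect_fiducials(beats[1])
        t0 = beats[1].onset_time_s
        for name, attr in (("systolic", "systolic_peak"),
                           ("notch", "dicrotic_notch"),
                           ("dicrotic", "dicrotic_peak"),
                           ("max_slope", "max_slope_point")):
            det = getattr(f, attr)[0] - t0
            assert abs(det - truth[name]) <= 1.0 / FS, name

    def test_monotone_rise_fall_beat_flagged_degenerate(self):
        t = np.arange(0, 0.8, 1 / FS)
        hump = np.exp(-0.5 * ((t - 0.25) / 0.1) ** 2)
        beat = Beat(0, hump, FS)
        with pytest.raises(DegenerateBeatError):
            detect_fiducials(beat)

    def test_first_of_equal_early_maxima_is_systolic(self):
        t = np.arange(0, 0.8, 1 / FS)
        two = (np.exp(-0.5 * ((t - 0.15) / 0.03) ** 2)
               + np.exp(-0.5 * ((t - 0.30) / 0.03) ** 2)
               + 0.3 * np.exp(-0.5 * ((t - 0.55) / 0.05) ** 2))
        f = detect_fiducials(Beat(0, two, FS))
        assert abs(f.systolic_peak[0] - 0.15) <= 2.0 / FS

    def test_ordering_invariant_enforced(self):
        with pytest.raises(DegenerateBeatError):
            FiducialPoints(
                diastolic_point_1=(0.0, 0.0),
                max_slope_point=(0.10, 5.0),
                systolic_peak=(0.05, 1.0),   # out of order
                dicrotic_notch=(0.30, 0.2),
                dicrotic_peak=(0.40, 0.4),
                diastolic_point_2=(0.80, 0.0))


class TestComputeFeatures:
    @pytest.fixture
    def fiducials(self):
        return FiducialPoints(
            diastolic_point_1=(0.0, 0.1),
            max_slope_point=(0.08, 6.0),
            systolic_peak=(0.15, 1.1),
            dicrotic_notch=(0.30, 0.35),
            dicrotic_peak=(0.40, 0.6),
            diastolic_point_2=(0.80, 0.12))

    def test_heart_rate_from_peak_to_peak_interval(self, fiducials):
        fv = compute_features(fiducials, prev_systolic_time=0.15 - 0.8,
                              sampling_rate=FS)
        assert fv.heart_rate_bpm == pytest.approx(75.0)

    def test_augmentation_index_is_relative_amplitude_ratio(self, fiducials):
        fv = compute_features(fiducials, -0.65, FS)
        assert fv.aug_index == pytest.approx(1.0 / 0.5)  # (1.1-.1)/(.6-.1)
        fv2 = compute_features(fiducials, -0.65, FS,
                               ai_convention="dicrotic_over_systolic")
        assert fv2.aug_index == pytest.approx(0.5)

    def test_time_intervals_are_landmark_differences(self, fiducials):
        fv = compute_features(fiducials, -0.65, FS)
        assert fv.t1_s == pytest.approx(0.15)
        assert fv.t2_s == pytest.approx(0.25)
        assert fv.t3_s == pytest.approx(0.40)

    def test_non_positive_dicrotic_offset_rejected(self, fiducials):
        bad = dataclasses.replace(fiducials, dicrotic_peak=(0.40, 0.05),
                                  dicrotic_notch=(0.30, 0.02))
        with pytest.raises(DegenerateBeatError, match="augmentation"):
            compute_features(bad, -0.65, FS)


class TestInvariances:
    def _features_of(self, signal):
        fv, _ = featurize_recording(signal, FS)
        return fv.as_array()

    def test_time_shift_leaves_features_unchanged(self, clean_recording):
        rec, _ = clean_recording
        x = rec.channels[1]
        k = 37
        base = self._features_of(x[:-k])
        shifted = self._features_of(x[k:])
        np.testing.assert_allclose(shifted, base, rtol=0.02, atol=1e-6)

    def test_amplitude_scaling_covariance(self, clean_recording):
        rec, _ = clean_recording
        x = rec.channels[1]
        c = 3.7
        base = dict(zip(FEATURE_NAMES, self._features_of(x)))
        scaled = dict(zip(FEATURE_NAMES, self._features_of(c * x)))
        for name in ("systolic_peak_amp", "dicrotic_peak_amp", "dp1_amp",
                     "dp2_amp", "notch_amp", "max_slope"):
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-6)
        for name in ("heart_rate_bpm", "aug_index", "t1_s", "t2_s", "t3_s"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)


class TestFeaturizeRecording:
    def test_identical_beats_median_equals_single_beat(self):
        params = beat_params_from_bp(118, 70, hr_bpm=75.0)
        signal, _ = _periodic_train(params, 8)
        fv, n = featurize_recording(signal, FS)
        assert n >= 5
        assert fv.heart_rate_bpm == pytest.approx(75.0, rel=0.02)

    def test_rejects_too_few_beats(self):
        params = beat_params_from_bp(118, 70, hr_bpm=75.0)
        signal, _ = _periodic_train(params, 3)
        with pytest.raises(RecordRejectedError):
            featurize_recording(signal, FS, min_beats=5)

    def test_recovered_t1_close_to_ground_truth(self, clean_recording):
        rec, truth = clean_recording
        from pulsebp.emd import denoise
        fv, _ = featurize_recording(denoise(rec.channels[1], FS), FS)
        assert abs(fv.t1_s - truth.median_intervals()["t1_s"]) <= 2.0 / FS

    def test_median_robust_to_one_outlier_beat(self):
        params = beat_params_from_bp(118, 70, hr_bpm=75.0)
        signal, _ = _periodic_train(params, 10)
        fv_base, _ = featurize_recording(signal, FS)
        corrupted = signal.copy()
        y_len = int(round(params.beat_period_s * FS))
        corrupted[4 * y_len: 4 * y_len + 30] += 0.3  # spike inside one beat
        fv_corr, _ = featurize_recording(corrupted, FS)
        assert fv_corr.t1_s == pytest.approx(fv_base.t1_s, abs=1.01 / FS)
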