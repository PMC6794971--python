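"""Peak detection, minute features, accelerometer statistics, matrix assembly."""

import numpy as np
import pytest
from scipy.stats import kurtosis as scipy_kurtosis

import wearstate as ws
from wearstate.features import (
    SAMPLES_PER_MINUTE,
    PeakParams,
    detect_peaks,
    minute_peak_features,
    subject_accel_features,
)
from wearstate.io import CHANNEL_BLOCKS, channel_slices

from conftest import brute_force_peaks


class TestDetectPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert len(detect_peaks(np.arange(100.0))) == 0

    def test_sampled_sinusoid_matches_brute_force_count(self):
        """1.2 Hz sinusoid over 60 s at 10 Hz: one detected peak per cycle."""
        t = np.arange(600) / 10
        x = np.sin(2 * np.pi * 1.2 * t)
        params = PeakParams(threshold_k=0.0, min_distance=3)
        got = detect_peaks(x, params)
        expected = brute_force_peaks(x, 0.0, 3)
        np.testing.assert_array_equal(got, expected)
        assert len(got) == 72

    def test_refractory_suppression_keeps_larger(self):
        x = np.zeros(20)
        x[5], x[7] = 5.0, 7.0
        got = detect_peaks(x, PeakParams(threshold_k=0.0, min_distance=3))
        np.testing.assert_array_equal(got, [7])

    def test_tie_keeps_earlier_index(self):
        x = np.zeros(20)
        x[5] = x[7] = 6.0
        got = detect_peaks(x, PeakParams(threshold_k=0.0, min_distance=3))
        np.testing.assert_array_equal(got, [5])

    def test_agrees_with_exhaustive_oracle_on_random_series(self):
        rng = np.random.default_rng(123)
        for min_distance in (1, 2, 3, 10):
            x = rng.standard_normal(10_000)
            params = PeakParams(threshold_k=1.0, min_distance=min_distance)
            np.testing.assert_array_equal(
                detect_peaks(x, params), brute_force_peaks(x, 1.0, min_distance))

    def test_short_input_empty(self):
        assert len(detect_peaks([1.0, 2.0])) == 0


class TestMinuteFeatures:
    def test_empty_minute_is_all_zero(self):
        out = minute_peak_features(np.zeros(600), [], "ecg")
        np.testing.assert_array_equal(out, [[0, 0, 0, 0]])

    def test_hand_computed_amplitudes(self):
        x = np.zeros(600)
        peaks = np.array([10, 200, 400])
        x[peaks] = [2.0, 4.0, 8.0]
        out = minute_peak_features(x, peaks, "emg")
        assert out.shape == (1, 3)
        assert out[0, 0] == 3
        assert out[0, 1] == pytest.approx(14 / 3, abs=1e-3)    # mean(2, 4, 8)
        assert out[0, 2] == pytest.approx(3.0)                  # mean(|4-2|, |8-4|)

    def test_resting_rate_for_evenly_spaced_peaks(self):
        peaks = np.arange(0, 600, 10)  # one peak per second
        out = minute_peak_features(np.ones(600), peaks, "ecg")
        assert out[0, 3] == pytest.approx(1.0)

    def test_single_peak_differ_mean_zero(self):
        out = minute_peak_features(np.ones(600), [300], "bvp")
        assert out[0, 2] == 0.0

    def test_trailing_partial_minute_dropped(self):
        out = minute_peak_features(np.zeros(1599), [], "resp")
        assert out.shape == (2, 3)


class TestSubjectAccelFeatures:
    def test_identical_axes_correlation_clipped_to_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        feats = subject_accel_features(np.stack([x, x, -x], axis=1))
        corr_xy, corr_xz = feats[12], feats[13]
        assert corr_xy == 1.0   # raw mixed moment is N/(N-1) > 1 -> clipped
        assert corr_xz == -1.0

    def test_printed_correlation_form_exceeds_one(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        feats = subject_accel_features(np.stack([x, x, -x], axis=1), printed_forms=True)
        assert feats[12] == pytest.approx(500 / 499)

    def test_gaussian_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(99)
        a = rng.standard_normal((100_000, 3))
        feats = subject_accel_features(a)
        kurts = feats[6:9]
        assert np.abs(kurts).max() < 0.05
        # cross-check against the reference implementation
        np.testing.assert_allclose(
            kurts, scipy_kurtosis(a, axis=0, fisher=True, bias=True), atol=1e-12)

    def test_crest_factor_of_near_constant_axis(self):
        """crest = max(x) / sqrt(sum(x^2)/(N-1)) -> sqrt((N-1)/N) for constant x."""
        n = 1000
        c = 3.0
        x = np.full(n, c)
        crest = x.max() / np.sqrt(np.sum(x**2) / (n - 1))
        assert crest == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)
        # through the API the constant axis is rejected as undefined instead
        with pytest.raises(ValueError, match="axis 'x'"):
            subject_accel_features(np.stack([x, np.random.default_rng(0).standard_normal(n),
                                             np.arange(n, dtype=float)], axis=1))

    def test_population_std_normalization(self):
        a = np.stack([np.array([0.0, 2.0]), np.array([1.0, 3.0]),
                      np.array([5.0, 1.0])], axis=1)
        feats = subject_accel_features(a)
        np.testing.assert_allclose(feats[3:6], a.std(axis=0))  # 1/N form


class TestAssembleFeatureMatrix:
    def test_ten_minute_subject_yields_6000_rows(self, cohort_params):
        rec = ws.generate_subject("solo", cohort_params, seed=11)
        ds = ws.assemble_feature_matrix([rec])
        assert ds.features.shape == (6000, 28)
        assert ds.n_samples == 6000

    def test_column_blocks_are_4_3_3_3_15(self, features):
        assert sum(CHANNEL_BLOCKS.values()) == 28
        slices = channel_slices()
        assert [s.stop - s.start for s in slices.values()] == [4, 3, 3, 3, 15]

    def test_minute_broadcast_invariant(self, features):
        """Within one subject-minute the 4 ECG columns take a single value."""
        df = features.to_frame()
        one = df[df.subject_id == "S1"].iloc[:SAMPLES_PER_MINUTE]
        for col in ("ecg_peaks", "ecg_avg_amplitude", "ecg_differ_mean", "ecg_resting"):
            assert one[col].nunique() == 1

    def test_subject_broadcast_invariant(self, features):
        df = features.to_frame()
        accl_cols = [c for c in df.columns if c.startswith("accl_")]
        assert len(accl_cols) == 15
        for _, grp in df.groupby("subject_id"):
            assert (grp[accl_cols].nunique() == 1).all()

    def test_differ_mean_nonnegative(self, features):
        for col in ("ecg_differ_mean", "emg_differ_mean", "resp_differ_mean",
                    "bvp_differ_mean"):
            assert (features.to_frame()[col] >= 0).all()

    def test_sub_minute_recording_excluded_with_warning(self, cohort_params):
        from dataclasses import replace

        short = replace(cohort_params, class_durations_s=np.full(5, 8.0))
        rec = ws.generate_subject("tiny", short, seed=2)
        with pytest.warns(UserWarning, match="shorter than one minute"):
            ds = ws.assemble_feature_matrix([rec])
        assert ds.n_samples == 0
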