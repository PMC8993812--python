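import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alscore.accel import (
    FRAME_SAMPLES,
    N_FFT,
    TBVM_COEFFICIENTS,
    Uniform1HzScaler,
    accel_frames,
    accel_spectrogram,
    block_average_1hz,
    fft1hz_features,
    tbvm,
    uniform1hz,
    vector_magnitude,
)
from alscore.io import AccelRecording


class TestVectorMagnitude:
    def test_3_4_5_triple(self):
        np.testing.assert_allclose(vector_magnitude([3.0], [4.0], [0.0]), [5.0])

    def test_zero_input(self):
        np.testing.assert_allclose(vector_magnitude([0.0], [0.0], [0.0]), [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            vector_magnitude([1, 2], [1], [1, 2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_axis_negation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 20))
        vm = vector_magnitude(x, y, z)
        np.testing.assert_allclose(vector_magnitude(-x, y, z), vm)
        np.testing.assert_allclose(vector_magnitude(x, -y, -z), vm)
        assert (vm >= 0).all()


class TestTbvm:
    def test_all_limbs_at_divisor_sum_printed_coefficients(self):
        vm = {limb: 717.9 for limb in ("LA", "LW", "RA", "RW")}
        assert tbvm(vm) == pytest.approx(7.000958, abs=1e-9)

    def test_zero_movement_gives_zero(self):
        assert tbvm({l: 0.0 for l in ("LA", "LW", "RA", "RW")}) == 0.0

    def test_left_wrist_coefficient_is_unity(self):
        vm = {"LA": 0.0, "RA": 0.0, "RW": 0.0, "LW": 717.9}
        assert tbvm(vm) == pytest.approx(1.0)
        assert TBVM_COEFFICIENTS.per_limb["LW"] == 1.0

    def test_missing_limb_rejected(self):
        with pytest.raises(ValueError, match="RW"):
            tbvm({"LA": 1.0, "LW": 1.0, "RA": 1.0})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 10.0))
    def test_linear_and_homogeneous(self, seed, c):
        rng = np.random.default_rng(seed)
        v = {l: float(rng.uniform(0, 1000)) for l in ("LA", "LW", "RA", "RW")}
        scaled = {l: c * x for l, x in v.items()}
        assert tbvm(scaled) == pytest.approx(c * tbvm(v), rel=1e-9, abs=1e-12)


class TestFft1hz:
    def _series(self, **overrides):
        base = {l: np.ones(60) for l in ("LA", "LW", "RA", "RW")}
        base.update(overrides)
        return base

    def test_output_length_is_8(self):
        assert fft1hz_features(self._series()).shape == (8,)

    def test_constant_series_has_zero_dominant_component(self):
        feats = fft1hz_features(self._series())
        assert np.allclose(feats[1::2], 0.0)
        assert np.allclose(feats[0::2], 1.0)  # mean level of the unit series

    def test_pure_sinusoid_dominant_magnitude_is_half_amplitude(self):
        n, a, cycles = 64, 3.0, 4
        t = np.arange(n)
        sig = a * np.sin(2 * np.pi * cycles * t / n)
        feats = fft1hz_features(self._series(LW=sig))
        # limb order LA, LW, RA, RW -> LW occupies features 2 and 3
        assert feats[3] == pytest.approx(a / 2.0, rel=1e-9)

    def test_circular_shift_invariance(self, rng):
        series = self._series(RA=rng.normal(size=50))
        shifted = dict(series)
        shifted["RA"] = np.roll(series["RA"], 13)
        np.testing.assert_allclose(
            fft1hz_features(series), fft1hz_features(shifted), atol=1e-12
        )

    def test_missing_limb_rejected(self):
        with pytest.raises(ValueError, match="missing limb"):
            fft1hz_features({"LA": np.ones(10)})


class TestUniform1hz:
    def _series(self, lengths):
        rng = np.random.default_rng(0)
        return {
            l: rng.normal(size=n) + 1.0
            for l, n in zip(("LA", "LW", "RA", "RW"), lengths)
        }

    def test_short_series_zero_padded(self):
        series = self._series([50, 70, 70, 70])
        vec = uniform1hz(series)
        assert vec.shape == (280,)
        np.testing.assert_array_equal(vec[50:70], 0.0)
        np.testing.assert_array_equal(vec[:50], series["LA"][:50])

    def test_long_series_truncated_to_70(self):
        series = self._series([90, 90, 90, 90])
        vec = uniform1hz(series)
        np.testing.assert_array_equal(vec[:70], series["LA"][:70])

    def test_training_self_standardization(self, rng):
        X = np.stack(
            [uniform1hz(self._series([60 + i, 70, 80, 65])) for i in range(20)]
        )
        # rows differ; standardize with training stats
        X = X + rng.normal(size=X.shape)
        scaler = Uniform1HzScaler()
        Z = scaler.fit_transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        sd = X.std(axis=0)
        np.testing.assert_allclose(Z.std(axis=0)[sd > 0], 1.0, atol=1e-12)


class TestAccelFraming:
    def _recording(self, seconds):
        n = int(seconds * 30)
        series = {l: np.ones((3, n)) for l in ("LA", "LW", "RA", "RW")}
        return AccelRecording("P", 0, series, 30)

    @pytest.mark.parametrize("seconds,expected", [(300, 4), (75, 1), (74, 0)])
    def test_frame_counts(self, seconds, expected):
        frames = accel_frames(self._recording(seconds))
        assert all(len(v) == expected for v in frames.values())
        for v in frames.values():
            assert all(len(f) == FRAME_SAMPLES for f in v)

    def test_one_hz_stream_rejected_for_framing(self):
        rec = AccelRecording("P", 0, {"LA": np.ones((3, 80))}, 1)
        with pytest.raises(ValueError, match="30 Hz"):
            accel_frames(rec)


class TestAccelSpectrogram:
    def test_shape_is_19_by_129(self, rng):
        assert accel_spectrogram(rng.normal(size=FRAME_SAMPLES)).shape == (19, 129)

    def test_zero_frame_gives_zero_spectrogram(self):
        np.testing.assert_array_equal(
            accel_spectrogram(np.zeros(FRAME_SAMPLES)), 0.0
        )

    def test_2hz_sinusoid_peaks_at_analytic_bin(self):
        t = np.arange(FRAME_SAMPLES) / 30.0
        spec = accel_spectrogram(np.sin(2 * np.pi * 2.0 * t))
        expected_bin = round(2.0 * N_FFT / 30.0)  # = 17
        assert (spec.argmax(axis=1) == expected_bin).all()

    def test_matches_brute_force_dft_window_by_window(self, rng):
        frame = rng.normal(size=FRAME_SAMPLES)
        spec = accel_spectrogram(frame)
        padded = np.pad(frame, (0, 210))
        for w in range(19):
            seg = padded[w * 120 : w * 120 + 210]
            # brute-force one-sided DFT magnitude with explicit exponentials
            k = np.arange(129)
            n = np.arange(N_FFT)
            seg_padded = np.pad(seg, (0, N_FFT - len(seg)))
            dft = (seg_padded[None, :] * np.exp(-2j * np.pi * k[:, None] * n / N_FFT)).sum(axis=1)
            np.testing.assert_allclose(spec[w], np.abs(dft), atol=1e-8)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="2250"):
            accel_spectrogram(np.zeros(100))


class TestBlockAverage:
    def test_30hz_minute_becomes_60_samples(self, rng):
        assert block_average_1hz(rng.normal(size=1800)).shape == (60,)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(block_average_1hz(np.full(90, 2.5)), 2.5)

    def test_trailing_partial_second_dropped(self):
        assert block_average_1hz(np.ones(95)).shape == (3,)
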