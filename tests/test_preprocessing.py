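import numpy as np
import pytest
from scipy import signal

from gaitspace import (
    TrialKey,
    TrialRecord,
    center_and_scale,
    detect_stance,
    lowpass_filter,
    preprocess_trial,
    time_normalize,
)
from gaitspace.errors import NoStanceError
from gaitspace.preprocessing import PreprocessConfig


def brute_force_stance(force, threshold):
    """Independent oracle: linear scan for the first supra-threshold episode."""
    above = [i for i, f in enumerate(force) if f >= threshold]
    if not above:
        return None
    start = above[0]
    end = start
    while end + 1 < len(force) and force[end + 1] >= threshold:
        end += 1
    return start, end


class TestDetectStance:
    def test_printed_trace(self):
        force = [0, 5, 20, 600, 400, 10, 0]
        assert detect_stance(force, 15.0) == (2, 4)
        assert detect_stance(force, 15.0) == brute_force_stance(force, 15.0)

    def test_all_zero(self):
        with pytest.raises(NoStanceError):
            detect_stance(np.zeros(10), 15.0)

    def test_two_episodes_warns_uses_first(self):
        force = [0, 20, 30, 0, 0, 40, 50, 0]
        with pytest.warns(UserWarning, match="first"):
            assert detect_stance(force, 15.0) == (1, 2)

    def test_half_sine_matches_scan(self):
        t = np.arange(0, 0.3, 1 / 240.0)
        force = 800.0 * np.sin(np.pi * t / 0.3)
        force[force < 0] = 0.0
        assert detect_stance(force, 15.0) == brute_force_stance(force, 15.0)


class TestLowpass:
    def test_dc_gain(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x), x, atol=1e-9)

    @pytest.mark.parametrize("freq,tol", [(1.0, 0.01), (50.0, 0.05)])
    def test_magnitude_response(self, freq, tol):
        """Filtered amplitude matches the designed filter's |H|^2 (filtfilt)."""
        fs, n = 240.0, 4800
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, cutoff=12.0, order=4, sample_rate=fs)
        sos = signal.butter(2, 12.0, fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward pass squares |H|
        mid = slice(n // 4, 3 * n // 4)  # exclude edge effects
        measured = np.abs(y[mid]).max()
        assert measured == pytest.approx(expected, rel=tol, abs=1e-4)

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(np.zeros(100), cutoff=120.0, sample_rate=240.0)
        with pytest.raises(ValueError, match="length"):
            lowpass_filter(np.zeros(5), order=4)


class TestTimeNormalize:
    def test_output_length(self):
        out = time_normalize(np.random.default_rng(0).normal(size=(57, 2, 3)))
        assert out.shape == (101, 2, 3)

    def test_linear_ramp_exact(self):
        x = np.linspace(2.0, 5.0, 60)
        out = time_normalize(x)
        np.testing.assert_allclose(out, np.linspace(2.0, 5.0, 101), atol=1e-9)

    def test_identity_at_native_length(self):
        x = np.sin(np.linspace(0, 3, 101))
        out = time_normalize(x)
        np.testing.assert_allclose(out, x, atol=1e-9)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_too_short(self):
        with pytest.raises(ValueError):
            time_normalize(np.zeros(1))

    def test_bandlimited_recovery_through_filter(self):
        """Filtering then resampling a < 6 Hz signal stays within 2% RMS."""
        fs = 240.0
        t = np.arange(int(0.3 * fs)) / fs
        x = np.sin(2 * np.pi * 3.0 * t)
        y = time_normalize(lowpass_filter(x, sample_rate=fs))
        expected = np.sin(2 * np.pi * 3.0 * np.linspace(t[0], t[-1], 101))
        rms = np.sqrt(np.mean((y - expected) ** 2)) / np.sqrt(np.mean(expected**2))
        assert rms < 0.02


class TestCenterAndScale:
    def _trial(self, pos):
        return TrialRecord(TrialKey("s", "a", 1), pos)

    def test_pelvis_centroid_zeroed(self):
        rng = np.random.default_rng(2)
        out = center_and_scale(self._trial(rng.normal(size=(20, 5, 3))), (1, 2), 1.8)
        centroid = out.positions[:, [0, 1], :].mean(axis=1)
        assert np.abs(centroid[:, :2]).max() < 1e-10  # horizontal axes only

    def test_height_scaling(self):
        pos = np.random.default_rng(3).normal(size=(10, 4, 3))
        a = center_and_scale(self._trial(pos), (1,), 1.0)
        b = center_and_scale(self._trial(pos), (1,), 2.0)
        np.testing.assert_allclose(b.positions, a.positions / 2.0, atol=1e-10)

    def test_translation_invariance(self):
        pos = np.random.default_rng(4).normal(size=(10, 4, 3))
        shifted = pos + np.array([5.0, -3.0, 0.0])
        a = center_and_scale(self._trial(pos), (1, 2), 1.8)
        b = center_and_scale(self._trial(shifted), (1, 2), 1.8)
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-10)

    def test_floor_at_zero(self):
        pos = np.random.default_rng(5).normal(size=(10, 4, 3)) + 3.0
        out = center_and_scale(self._trial(pos), (1,), 1.8)
        assert out.positions[:, :, 2].min() == pytest.approx(0.0, abs=1e-12)

    def test_bad_height(self):
        with pytest.raises(ValueError):
            center_and_scale(self._trial(np.zeros((5, 2, 3))), (1,), 0.0)


class TestPipeline:
    def test_raw_trial_end_to_end(self):
        from gaitspace import SyntheticConfig, generate_raw

        cfg = SyntheticConfig(
            subjects=2, trials_per_condition=1, markers=3, timepoints=31, effects=()
        )
        raw, _, heights = generate_raw(cfg)
        out = preprocess_trial(raw[0], PreprocessConfig(timepoints=101, height_m=heights,
                                                        pelvis_markers=(1, 2)))
        assert out.positions.shape == (101, 3, 3)
        assert out.force is None

    def test_force_required(self):
        t = TrialRecord(TrialKey("s", "a", 1), np.zeros((50, 2, 3)))
        with pytest.raises(ValueError, match="force"):
            preprocess_trial(t)
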