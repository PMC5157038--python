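"""Closed-form and property checks of the envelope estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muresp import (
    Recording,
    bandpass_zero_phase,
    compute_envelope,
    hilbert_envelope,
    moving_average,
    rectify,
)

FS = 1000.0


def _tone(freq, fs=FS, duration=10.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _interior(x, fs=FS, margin_s=1.0):
    m = int(margin_s * fs)
    return x[m:-m]


class TestBandpass:
    def test_passband_tone_preserved(self):
        y = _interior(bandpass_zero_phase(_tone(10.0), FS, 8, 14))
        amp = np.sqrt(2) * np.sqrt(np.mean(y**2))  # steady-state amplitude
        assert 0.95 <= amp <= 1.0 + 1e-6

    def test_stopband_tone_suppressed(self):
        y = bandpass_zero_phase(_tone(3.0), FS, 8, 14)
        assert np.max(np.abs(_interior(y))) <= 0.05

    def test_zero_phase_no_lag(self):
        x = bandpass_zero_phase(_tone(10.0), FS, 8, 14)  # band-limited input
        y = bandpass_zero_phase(x, FS, 8, 14)
        xi, yi = _interior(x), _interior(y)
        lags = np.arange(-20, 21)
        xc = [np.dot(xi[20 + l : len(xi) - 20 + l], yi[20 : len(yi) - 20]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_time_reversal_invariance(self, rng):
        """Away from the edges, filtering the time-reversed signal and
        reversing back reproduces the forward result (zero net phase)."""
        x = rng.standard_normal(10000)
        y = bandpass_zero_phase(x, FS, 8, 14)
        y_rev = bandpass_zero_phase(x[::-1], FS, 8, 14)[::-1]
        # edge transients decay with the slowest pole (~3000 samples to 1e-9)
        np.testing.assert_allclose(y[3000:-3000], y_rev[3000:-3000], atol=1e-8)

    @pytest.mark.parametrize("low,high", [(0, 14), (14, 8), (8, 600)])
    def test_invalid_edges(self, low, high):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(5000), FS, low, high)

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass_zero_phase(np.zeros(10), FS, 8, 14)


class TestRectify:
    def test_values_and_symmetry(self):
        np.testing.assert_array_equal(rectify([-1, 2, -3]), [1, 2, 3])
        x = np.linspace(0, 1, 50)
        np.testing.assert_array_equal(rectify(x), x)
        odd = _tone(7.0, duration=1.0)
        np.testing.assert_allclose(rectify(odd), rectify(-odd))


class TestMovingAverage:
    def test_constant_preserved(self):
        np.testing.assert_allclose(moving_average(np.full(500, 3.7), FS), 3.7)

    def test_rectified_sine_plateau(self):
        """Mean of |sin| over full periods is 2/pi."""
        y = moving_average(np.abs(_tone(10.0)), FS, 0.1)
        plateau = _interior(y)
        np.testing.assert_allclose(plateau, 2 / np.pi, rtol=0.01)

    def test_impulse_response_is_window(self):
        x = np.zeros(501)
        x[250] = 1.0
        y = moving_average(x, FS, 0.1)  # 100 samples of weight over 101 taps
        assert y[250] == pytest.approx(1 / 100)
        np.testing.assert_allclose(y[205:296], 1 / 100)  # interior taps
        assert y[200] == pytest.approx(0.5 / 100)  # half-weight end taps
        assert y.sum() == pytest.approx(1.0)

    def test_window_errors(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), FS, 0.1)  # window > signal
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), 2.0, 0.1)  # window < one sample


class TestHilbertEnvelope:
    def test_constant_amplitude_tone(self):
        env = hilbert_envelope(_tone(10.0, amp=2.5))
        np.testing.assert_allclose(_interior(env), 2.5, rtol=0.01)

    def test_am_tone_recovery(self):
        t = np.arange(int(10 * FS)) / FS
        modulator = 1 + 0.5 * np.cos(2 * np.pi * 1.0 * t)
        env = hilbert_envelope(modulator * np.sin(2 * np.pi * 10.0 * t))
        np.testing.assert_allclose(_interior(env), _interior(modulator), rtol=0.02)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hilbert_envelope(np.array([1.0, np.nan, 2.0]))


@pytest.fixture(scope="module")
def tone_recording():
    data = np.vstack([_tone(10.0, amp=5.0), _tone(10.0, amp=5.0), np.zeros(int(10 * FS))])
    return Recording(["C3", "C4", "EOG"], FS, data, [5.0])


class TestComputeEnvelope:
    def test_methods_differ_by_two_over_pi(self, tone_recording):
        rs = compute_envelope(tone_recording, "C3", "alpha", "rectify_smooth")
        hb = compute_envelope(tone_recording, "C3", "alpha", "hilbert_am")
        ratio = _interior(rs.values) / _interior(hb.values)
        np.testing.assert_allclose(ratio, 2 / np.pi, rtol=0.02)

    def test_zero_signal_zero_envelope(self, tone_recording):
        env = compute_envelope(tone_recording, "EOG", "alpha")
        np.testing.assert_allclose(env.values, 0.0, atol=1e-10)

    def test_flat_modulation_flat_envelope(self, clean_recording):
        """d = r = 0, no noise: envelope coefficient of variation <= 0.1."""
        rec, _ = clean_recording
        flat = rec.copy()
        # rebuild with no modulation
        from muresp import ModulationParams, Scenario, simulate_recording

        sc = Scenario(
            fs=250.0, imi=2.0, n_triggers=12, jitter_sd=0.0, noise_sd=0.0,
            blink_rate=0.0, eog_noise_sd=0.0,
            bands={
                "alpha": ModulationParams(band="alpha", a_base=15.0, depth=0.0, rebound=0.0),
                "beta": ModulationParams(band="beta", a_base=6.0, depth=0.0, rebound=0.0),
            },
        )
        flat, _ = simulate_recording(sc, seed=5)
        for method in ("rectify_smooth", "hilbert_am"):
            env = compute_envelope(flat, "C3", "alpha", method)
            vals = _interior(env.values, fs=250.0)
            assert vals.std() / vals.mean() <= 0.1

    @pytest.mark.parametrize("method", ["rectify_smooth", "hilbert_am"])
    def test_nonnegative_and_length_preserving(self, noisy_recording, method):
        rec, _ = noisy_recording
        env = compute_envelope(rec, "C3", "beta", method)
        assert env.values.shape == rec.get_channel("C3").shape
        assert np.all(env.values >= 0)

    def test_unknown_inputs_rejected(self, tone_recording):
        with pytest.raises(KeyError):
            compute_envelope(tone_recording, "Cz", "alpha")
        with pytest.raises(KeyError):
            compute_envelope(tone_recording, "C3", "gamma")
        with pytest.raises(ValueError):
            compute_envelope(tone_recording, "C3", "alpha", "wavelet")

    def test_case_insensitive_channel(self, tone_recording):
        env = compute_envelope(tone_recording, "c3", "alpha")
        assert env.channel == "C3"


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 2**16))
def test_scaling_equivariance(scale, seed):
    """envelope(c*x) = c*envelope(x) for c > 0, for both estimators."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(3000)
    rec1 = Recording(["C3"], FS, x[None, :], [1.5])
    rec2 = Recording(["C3"], FS, scale * x[None, :], [1.5])
    for method in ("rectify_smooth", "hilbert_am"):
        e1 = compute_envelope(rec1, "C3", "alpha", method).values
        e2 = compute_envelope(rec2, "C3", "alpha", method).values
        np.testing.assert_allclose(e2, scale * e1, rtol=1e-9, atol=1e-12)
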