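"""Epoch segmentation, retention rules, and block averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muresp import (
    EnvelopeSignal,
    EpochSet,
    InsufficientEpochsError,
    apply_retention,
    block_average,
    compute_envelope,
    inter_movement_durations,
    retention_rate,
    segment_epochs,
)
from muresp.epoching import (
    REJECTED_ARTIFACT,
    REJECTED_EDGE,
    REJECTED_FIRST,
    REJECTED_TIMING,
    RETAINED,
    retention_flags,
)


def _flat_envelope(duration=60.0, fs=1000.0, value=1.0, band="alpha", channel="C3"):
    n = int(duration * fs)
    return EnvelopeSignal(band=band, channel=channel, fs=fs, values=np.full(n, value),
                          method="rectify_smooth")


def _epochset(imd, eog_peak=None, n_samp=10, fs=10.0):
    imd = np.asarray(imd, dtype=float)
    n = imd.size
    if eog_peak is None:
        eog_peak = np.zeros(n)
    return EpochSet(
        window=(-0.5, 0.5), fs=fs,
        epochs=np.zeros((n, n_samp)),
        imd=imd, eog_peak=np.asarray(eog_peak, dtype=float),
        flags=np.array([RETAINED] * n, dtype=object),
    )


class TestInterMovementDurations:
    def test_arithmetic(self):
        out = inter_movement_durations(np.array([0.0, 2.1, 4.7, 6.6]))
        assert np.isnan(out[0])
        np.testing.assert_allclose(out[1:], [2.1, 2.6, 1.9])

    def test_single_trigger(self):
        out = inter_movement_durations(np.array([3.0]))
        assert out.shape == (1,) and np.isnan(out[0])

    def test_sub_session_boundaries_reset(self):
        """The first movement after each rest break has no defined duration."""
        tr = np.array([1.0, 3.0, 5.0, 65.0, 67.0])
        out = inter_movement_durations(tr, run_starts=[60.0])
        assert np.isnan(out[0]) and np.isnan(out[3])
        np.testing.assert_allclose(out[[1, 2, 4]], 2.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            inter_movement_durations(np.array([2.0, 1.0]))

    def test_simulator_jitter_free(self, clean_recording):
        rec, _ = clean_recording
        out = inter_movement_durations(rec.triggers)
        np.testing.assert_allclose(out[1:], 2.0)


class TestSegmentEpochs:
    def test_epoch_sample_count(self):
        env = _flat_envelope(duration=30.0, fs=1000.0)
        es = segment_epochs(env, np.zeros_like(env.values), [5.0, 10.0], window=(-1.5, 2.0))
        assert es.epochs.shape == (2, 3500)
        np.testing.assert_allclose(es.times[0], -1.5)

    def test_edge_trigger_flagged(self):
        env = _flat_envelope(duration=30.0, fs=1000.0)
        es = segment_epochs(env, np.zeros_like(env.values), [0.5, 10.0, 29.0])
        assert list(es.flags) == [REJECTED_EDGE, RETAINED, REJECTED_EDGE]

    def test_all_triggers_inside(self, noisy_recording):
        rec, _ = noisy_recording
        env = compute_envelope(rec, "C3", "alpha")
        es = segment_epochs(env, rec.get_channel("EOG"), rec.triggers)
        assert es.counts()[REJECTED_EDGE] == 0
        assert es.n_triggers == len(rec.triggers)

    def test_eog_peak_is_window_max_abs(self):
        env = _flat_envelope(duration=20.0, fs=100.0)
        eog = np.zeros_like(env.values)
        eog[int(10.5 * 100)] = -400.0  # negative deflection inside the window
        es = segment_epochs(env, eog, [10.0], window=(-1.5, 2.0))
        assert es.eog_peak[0] == 400.0

    def test_no_trigger_in_bounds(self):
        env = _flat_envelope(duration=2.0, fs=100.0)
        with pytest.raises(ValueError, match="no trigger"):
            segment_epochs(env, np.zeros_like(env.values), [0.1])


class TestRetention:
    def test_enumeration_oracle(self, rng):
        """Flags match an independent brute-force rule application."""
        imi = 2.0
        n = 200
        imd = np.concatenate([[np.nan], imi + rng.uniform(-1.0, 1.0, n - 1)])
        eog = rng.uniform(0, 600, n)
        flags = retention_flags(imd, eog, imi)
        for k in range(n):
            if np.isnan(imd[k]):
                expect = REJECTED_FIRST
            elif eog[k] >= 300.0:
                expect = REJECTED_ARTIFACT
            elif abs(imd[k] - imi) >= 0.5:
                expect = REJECTED_TIMING
            else:
                expect = RETAINED
            assert flags[k] == expect

    def test_spec_deviation_pattern(self):
        """Deviations [0.1, 0.6, 0.1, 0.6, 0.0] with clean EOG: 3 of 5 kept."""
        es = _epochset(2.0 + np.array([0.1, 0.6, 0.1, 0.6, 0.0]))
        es = apply_retention(es, 2.0)
        assert int(es.retained_mask.sum()) == 3
        assert retention_rate(es) == pytest.approx(60.0)

    def test_artifact_overrides_timing(self):
        es = _epochset([2.9], eog_peak=[350.0])  # bad timing AND artifact
        es = apply_retention(es, 2.0)
        assert es.flags[0] == REJECTED_ARTIFACT

    @pytest.mark.parametrize(
        "eog,imd,expected",
        [
            (300.0, 2.0, REJECTED_ARTIFACT),   # threshold value rejected
            (299.99, 2.0, RETAINED),
            (0.0, 2.5, REJECTED_TIMING),       # deviation exactly 0.5 rejected
            (0.0, 2.4999, RETAINED),
        ],
    )
    def test_strict_boundaries(self, eog, imd, expected):
        es = apply_retention(_epochset([imd], eog_peak=[eog]), 2.0)
        assert es.flags[0] == expected

    def test_edge_flag_preserved(self):
        es = _epochset([2.0, 2.0])
        es.flags[0] = REJECTED_EDGE
        es = apply_retention(es, 2.0)
        assert es.flags[0] == REJECTED_EDGE and es.flags[1] == RETAINED

    def test_flag_accounting(self, noisy_recording):
        rec, _ = noisy_recording
        env = compute_envelope(rec, "C4", "beta")
        es = apply_retention(segment_epochs(env, rec.get_channel("EOG"), rec.triggers), 2.0)
        assert sum(es.counts().values()) == es.n_triggers

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        dev_lo=st.floats(0.1, 0.5),
        dev_hi=st.floats(0.5, 1.5),
        eog_lo=st.floats(50, 300),
        eog_hi=st.floats(300, 800),
    )
    def test_retention_monotone_in_thresholds(self, seed, dev_lo, dev_hi, eog_lo, eog_hi):
        """Raising either threshold never decreases the retained count."""
        r = np.random.default_rng(seed)
        es = _epochset(2.0 + r.uniform(-1, 1, 50), eog_peak=r.uniform(0, 600, 50))
        n_lo = apply_retention(es, 2.0, dev_lo, eog_lo).retained_mask.sum()
        n_hi = apply_retention(es, 2.0, dev_hi, eog_hi).retained_mask.sum()
        assert n_hi >= n_lo


class TestRetentionRate:
    def test_all_retained(self):
        es = apply_retention(_epochset([2.0, 2.0, 2.1]), 2.0)
        assert retention_rate(es) == pytest.approx(100.0)

    def test_first_excluded_from_denominator(self):
        es = apply_retention(_epochset([np.nan, 2.0, 2.9]), 2.0)
        assert retention_rate(es) == pytest.approx(50.0)

    def test_empty_denominator(self):
        es = apply_retention(_epochset([np.nan]), 2.0)
        with pytest.raises(ValueError):
            retention_rate(es)


class TestBlockAverage:
    def test_partition_and_remainder(self):
        es = apply_retention(_epochset([2.0] * 131), 2.0)  # 130 retained + 1 first
        responses = block_average(es, block_size=60)
        assert len(responses) == 2
        assert all(r.n_epochs == 60 for r in responses)

    def test_mean_identity_for_identical_epochs(self):
        es = _epochset([2.0] * 61, n_samp=20)
        trace = np.sin(np.linspace(0, 3, 20))
        es.epochs[:] = trace
        es = apply_retention(es, 2.0)
        resp = block_average(es, block_size=60)[0]
        np.testing.assert_allclose(resp.values, trace)

    def test_insufficient_epochs(self):
        es = apply_retention(_epochset([2.0] * 10), 2.0)
        with pytest.raises(InsufficientEpochsError):
            block_average(es, block_size=60)

    def test_response_extrema_near_true_latencies(self, clean_recording):
        """High-SNR response: minimum near the ERD centre, maximum near the
        rebound centre."""
        rec, truth = clean_recording
        env = compute_envelope(rec, "C3", "alpha")
        es = apply_retention(segment_epochs(env, rec.get_channel("EOG"), rec.triggers), 2.0)
        resp = block_average(es)[0]
        t = resp.times
        mp = truth.params[("C3", "alpha")]
        pre = (t >= -1.5) & (t < 0)
        post = (t >= 0) & (t < 2.0)
        t_min = t[pre][np.argmin(resp.values[pre])]
        t_max = t[post][np.argmax(resp.values[post])]
        assert abs(t_min - mp.t_erd) <= 0.1
        assert abs(t_max - mp.t_ers) <= 0.1

    def test_averaging_reduces_variance(self, noisy_recording):
        """Pointwise variance across block means is below the pointwise
        variance across individual epochs."""
        rec, _ = noisy_recording
        env = compute_envelope(rec, "C3", "alpha")
        es = apply_retention(segment_epochs(env, rec.get_channel("EOG"), rec.triggers), 2.0)
        responses = block_average(es, block_size=10)
        assert len(responses) >= 3
        block_means = np.vstack([r.values for r in responses])
        var_blocks = block_means.var(axis=0, ddof=1).mean()
        var_epochs = es.epochs[es.retained_mask].var(axis=0, ddof=1).mean()
        assert var_blocks <= var_epochs
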