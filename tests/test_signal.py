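"""Preprocessing chain: averaging, asymmetry, FIR, SMAR, detrend, resample."""

import numpy as np
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import nfasym.signal as sig
from nfasym.signal import ArtifactConfig, FilterSpec, MaskedSeries


class TestHemisphereAveraging:
    def test_identical_channels_pass_through(self):
        hbo = np.full((8, 10), 3.7)
        left, right = sig.average_hemispheres(hbo)
        np.testing.assert_allclose(left.values, 3.7)
        np.testing.assert_allclose(right.values, 3.7)

    def test_hand_computed_sample(self):
        hbo = np.array([[1.0], [2.0], [3.0], [4.0], [0.0], [1.0], [0.0], [1.0]])
        left, right = sig.average_hemispheres(hbo)
        assert left.values[0] == 2.5
        assert right.values[0] == 0.5

    def test_matches_brute_force_loop(self, rng):
        """Vectorized means equal a per-sample Python-loop oracle."""
        hbo = rng.normal(size=(8, 100))
        left, right = sig.average_hemispheres(hbo)
        for t in range(100):
            assert left.values[t] == pytest.approx(sum(hbo[c, t] for c in range(4)) / 4, abs=1e-12)
            assert right.values[t] == pytest.approx(sum(hbo[c, t] for c in range(4, 8)) / 4, abs=1e-12)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="8 channel rows"):
            sig.average_hemispheres(np.zeros((6, 10)))

    def test_invalid_channel_samples_propagate(self):
        hbo = np.zeros((8, 5))
        valid = np.ones((8, 5), dtype=bool)
        valid[2, 3] = False  # left channel hit at sample 3
        left, right = sig.average_hemispheres(hbo, valid)
        assert not left.valid[3]
        assert right.valid[3]


class TestAsymmetry:
    def test_equal_hemispheres_give_zero(self):
        a = sig.compute_asymmetry(np.ones(5), np.ones(5))
        np.testing.assert_array_equal(a.values, 0.0)

    def test_left_minus_right(self):
        a = sig.compute_asymmetry(np.array([0.8]), np.array([0.3]))
        assert a.values[0] == pytest.approx(0.5)

    @given(hnp.arrays(np.float64, 20, elements=st.floats(-10, 10)),
           hnp.arrays(np.float64, 20, elements=st.floats(-10, 10)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetry(self, l, r):
        ab = sig.compute_asymmetry(l, r).values
        ba = sig.compute_asymmetry(r, l).values
        np.testing.assert_array_equal(ab, -ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            sig.compute_asymmetry(np.zeros(4), np.zeros(5))

    def test_invalid_iff_either_invalid(self):
        l = MaskedSeries(np.zeros(4), [True, False, True, True])
        r = MaskedSeries(np.zeros(4), [True, True, False, True])
        a = sig.compute_asymmetry(l, r)
        np.testing.assert_array_equal(a.valid, [True, False, False, True])


class TestLowpass:
    def test_unity_dc_gain_on_constant(self):
        y = sig.lowpass(np.full(200, 2.5)).values
        np.testing.assert_allclose(y, 2.5, atol=1e-12)

    def test_kernel_normalized_to_unit_sum(self):
        assert sig.design_fir(FilterSpec()).sum() == pytest.approx(1.0, abs=1e-12)

    def test_impulse_response_is_the_kernel(self):
        kernel = sig.design_fir(FilterSpec())
        x = np.zeros(101)
        x[50] = 1.0
        y = sig.lowpass(x).values
        np.testing.assert_allclose(y[50 - 10:50 + 11], kernel, atol=1e-12)

    def test_stopband_attenuation_against_transfer_function(self):
        """0.9 Hz is attenuated >= 20 dB vs 0.01 Hz, on 600-sample sinusoids,
        and the measured gains match the kernel's transfer function."""
        spec = FilterSpec()
        kernel = sig.design_fir(spec)
        _, h = scipy.signal.freqz(kernel, fs=spec.sampling_rate, worN=[0.01, 0.9])
        t = np.arange(600) / spec.sampling_rate
        gains = []
        for f in (0.01, 0.9):
            y = sig.lowpass(np.sin(2 * np.pi * f * t), spec).values
            gains.append(np.abs(y[100:-100]).max())
        assert 20 * np.log10(gains[1] / gains[0]) <= -20.0
        assert gains[0] == pytest.approx(abs(h[0]), rel=0.02)
        assert gains[1] <= abs(h[1]) * 3  # leakage-dominated, same order

    def test_preserves_mean_of_long_stationary_series(self, rng):
        x = 1.7 + rng.normal(0, 0.5, 4000)
        y = sig.lowpass(x).values
        assert y.mean() == pytest.approx(x.mean(), abs=1e-3)
        # DC gain itself is exact
        assert sig.design_fir(FilterSpec()).sum() == pytest.approx(1.0, abs=1e-9)

    def test_group_delay_compensated(self):
        """A slow ramp passes with no lateral shift (zero-lag filtering)."""
        t = np.arange(300) / 2.0
        y = sig.lowpass(0.1 * t).values
        np.testing.assert_allclose(y[30:-30], 0.1 * t[30:-30], atol=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sig.lowpass(np.zeros(10), FilterSpec(order=20))

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            FilterSpec(cutoff=1.5, sampling_rate=2.0)


class TestSmar:
    def test_constant_series_never_flagged(self):
        out = sig.smar(np.full(100, 1.0))
        assert out.valid.all()

    def test_clean_filtered_noise_not_flagged(self, rng):
        clean = sig.lowpass(rng.normal(0, 0.3, 600)).values
        assert sig.smar(clean).valid.all()

    def test_injected_spike_flags_only_its_windows(self, rng):
        """A 10-SD spike invalidates the windows covering it, nothing else."""
        clean = sig.lowpass(rng.normal(0, 0.3, 600)).values
        spiked = clean.copy()
        spiked[300] += 10 * clean.std()
        out = sig.smar(spiked)
        bad = np.flatnonzero(~out.valid)
        assert bad.size > 0
        w = int(round(ArtifactConfig().window_s * 2.0))
        assert bad.min() >= 300 - w + 1
        assert bad.max() <= 300 + w - 1
        assert out.valid[:280].all() and out.valid[320:].all()

    @given(hnp.arrays(np.float64, st.integers(12, 80), elements=st.floats(-5, 5)))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_never_flags_proportionate_series(self, x):
        """No sample is flagged when global peak-to-peak < k x global SD."""
        sd = x.std()
        ptp = x.max() - x.min()
        cfg = ArtifactConfig()
        if sd == 0 or ptp >= cfg.threshold_k * sd:
            return
        assert sig.smar(x, cfg).valid.all()

    def test_epoch_scorable_threshold(self):
        s = MaskedSeries(np.zeros(10), [True] * 4 + [False] * 6)
        assert not sig.epoch_scorable(s, ArtifactConfig(min_valid_fraction=0.5))
        assert sig.epoch_scorable(s, ArtifactConfig(min_valid_fraction=0.4))


class TestDetrend:
    def test_exact_line_maps_to_zero(self):
        t = np.arange(50, dtype=float)
        out = sig.detrend(3.0 * t + 2.0).values
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_constant_maps_to_zero(self):
        np.testing.assert_allclose(sig.detrend(np.full(30, 5.0)).values, 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        """Residuals equal the closed-form least-squares solution."""
        t = np.arange(80, dtype=float)
        x = 0.3 * t - 1.0 + rng.normal(0, 1, 80)
        out = sig.detrend(x).values
        # normal equations: beta = (A'A)^-1 A'x with A = [t, 1]
        A = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(A.T @ A, A.T @ x)
        np.testing.assert_allclose(out, x - A @ beta, atol=1e-9)

    def test_fit_uses_only_valid_samples(self):
        t = np.arange(40, dtype=float)
        x = 2.0 * t.copy()
        x[5] = 1000.0  # outlier, masked out
        s = MaskedSeries(x, valid=np.arange(40) != 5)
        out = sig.detrend(s)
        keep = s.valid
        np.testing.assert_allclose(out.values[keep], 0.0, atol=1e-9)

    def test_too_few_valid_samples_rejected(self):
        with pytest.raises(ValueError, match="2 valid samples"):
            sig.detrend(MaskedSeries(np.zeros(5), [True, False, False, False, False]))


class TestResample:
    def test_resample_to_own_grid_is_identity(self, rng):
        t = np.arange(44) / 2.0
        x = rng.normal(size=44)
        t2, x2 = sig.resample_epoch(t, x, 44)
        np.testing.assert_allclose(t2, t, atol=1e-9)
        np.testing.assert_allclose(x2, x, atol=1e-9)

    def test_line_stays_exactly_linear(self):
        t = np.arange(44) / 2.0
        for n in (10, 30, 100):
            t2, x2 = sig.resample_epoch(t, 2.0 * t + 1.0, n)
            np.testing.assert_allclose(x2, 2.0 * t2 + 1.0, atol=1e-9)

    def test_sinusoid_within_interpolation_error_bound(self):
        """Linear interpolation error <= (h^2/8) max|f''| for the new grid."""
        t = np.arange(44) / 2.0
        f = 0.2
        x = np.sin(2 * np.pi * f * t)
        t2, x2 = sig.resample_epoch(t, x, 30)
        h = 0.5  # source grid spacing bounds the interpolation error
        bound = h ** 2 / 8 * (2 * np.pi * f) ** 2
        np.testing.assert_allclose(x2, np.sin(2 * np.pi * f * t2), atol=bound)

    def test_two_d_rows_independent(self, rng):
        t = np.arange(20, dtype=float)
        x = rng.normal(size=(3, 20))
        _, x2 = sig.resample_epoch(t, x, 15)
        for i in range(3):
            _, row = sig.resample_epoch(t, x[i], 15)
            np.testing.assert_array_equal(x2[i], row)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            sig.resample_epoch(np.array([0.0]), np.array([1.0]), 10)
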