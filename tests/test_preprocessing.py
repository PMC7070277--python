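"""Preprocessing stages: filter design, windowed features, resampling,
normalization and wavelet denoising."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gaitgrnn.preprocessing import (
    BandpassSpec,
    DegenerateRangeError,
    FilterDesignError,
    apply_filter,
    design_bandpass,
    minmax_denormalize,
    minmax_normalize,
    resample_angles,
    wavelet_denoise,
    wavelet_lowpass,
    windowed_mean,
    windowed_rms,
)


class TestBandpassDesign:
    def test_meets_specification(self):
        """The design is verified against its own spec by direct
        frequency-response evaluation."""
        filt = design_bandpass(BandpassSpec())
        h = filt.frequency_response(np.array([20.0, 500.0, 10.0, 570.0, 100.0]))
        db = 20 * np.log10(np.abs(h))
        eps = 1e-6  # the pass-band constraint is binding by design
        assert db[0] >= -3.0 - eps and db[1] >= -3.0 - eps
        assert db[2] <= -20.0 and db[3] <= -20.0  # stop edges
        assert db[4] > -0.5  # mid-band

    def test_minimal_order_matches_formula(self):
        """The analog-prototype order equals the closed-form Butterworth
        bound evaluated on the warped, band-transformed edge frequencies."""
        spec = BandpassSpec()
        fs = spec.sample_rate
        warp = lambda f: 2 * fs * np.tan(np.pi * f / fs)
        wp1, wp2 = warp(spec.pass_lo), warp(spec.pass_hi)
        ws1, ws2 = warp(spec.stop_lo), warp(spec.stop_hi)
        w0sq, bw = wp1 * wp2, wp2 - wp1
        # lowpass-equivalent stop-band frequency (worst of the two edges)
        lp = lambda w: abs(w**2 - w0sq) / (bw * w)
        omega_s = min(lp(ws1), lp(ws2))
        num = 10 ** (spec.stop_atten_min / 10) - 1
        den = 10 ** (spec.pass_atten_max / 10) - 1
        n_formula = int(np.ceil(np.log10(num / den) / (2 * np.log10(omega_s))))
        assert design_bandpass(spec).order == n_formula

    def test_invalid_edges_rejected(self):
        with pytest.raises(FilterDesignError, match="band edges"):
            BandpassSpec(pass_lo=500.0, pass_hi=20.0)
        with pytest.raises(FilterDesignError, match="atten"):
            BandpassSpec(pass_atten_max=30.0, stop_atten_min=20.0)


class TestApplyFilter:
    def test_passband_tone_preserved_zero_phase(self):
        filt = design_bandpass()
        t = np.arange(8000) / 2000.0
        x = np.sin(2 * np.pi * 100.0 * t)
        y = apply_filter(filt, x)
        mid = slice(2000, 6000)
        amp = np.max(np.abs(y[mid]))
        assert amp == pytest.approx(1.0, rel=0.05)
        # zero phase: peak positions coincide with the input's
        assert np.max(np.abs(y[mid] - x[mid])) < 0.05

    def test_drift_removed(self):
        filt = design_bandpass()
        t = np.arange(8000) / 2000.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = apply_filter(filt, x)
        assert np.sqrt(np.mean(y**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_zeros_map_to_zeros(self):
        filt = design_bandpass()
        np.testing.assert_array_equal(apply_filter(filt, np.zeros(500)), np.zeros(500))

    def test_short_signal_rejected(self):
        filt = design_bandpass()
        with pytest.raises(ValueError, match="too short"):
            apply_filter(filt, np.zeros(10))


class TestWindowedFeatures:
    def test_rms_worked_example(self):
        np.testing.assert_allclose(
            windowed_rms(np.array([3.0, 4.0]), 2), [np.sqrt(12.5)], atol=1e-12
        )
        assert windowed_rms(np.array([3.0, 4.0]), 2)[0] == pytest.approx(3.5355339)

    def test_constant_signals(self):
        np.testing.assert_allclose(windowed_rms(np.full(40, -2.0), 20), [2.0, 2.0])
        np.testing.assert_allclose(windowed_mean(np.full(40, -2.0), 20), [-2.0, -2.0])
        assert windowed_mean(np.array([1.0, 3.0]), 2)[0] == 2.0

    def test_feature_rate_conversion(self):
        """20-sample windows turn a 2000 Hz second into 100 feature rows."""
        assert windowed_rms(np.ones(2000), 20).size == 100

    def test_trailing_partial_window_discarded(self):
        assert windowed_rms(np.ones(45), 20).size == 2
        assert windowed_rms(np.empty(0), 20).size == 0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            windowed_rms(np.ones(10), 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=hnp.arrays(
            float,
            st.integers(20, 100),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_rms_dominates_mean(self, x):
        """Power-mean inequality: RMS >= |mean| window by window."""
        rms, mean = windowed_rms(x, 10), windowed_mean(x, 10)
        assert np.all(rms >= np.abs(mean) - 1e-9)


class TestResampleAngles:
    def test_cubic_polynomial_reproduced(self):
        t = np.arange(400) / 2000.0
        x = 3.0 - 2.0 * t + 5.0 * t**2 - 1.5 * t**3
        series = resample_angles(t, x, out_rate=100.0)
        expected = 3.0 - 2.0 * series.t + 5.0 * series.t**2 - 1.5 * series.t**3
        np.testing.assert_allclose(series.values, expected, atol=1e-6)

    def test_output_count_at_100hz(self):
        t = np.arange(20000) / 2000.0  # 10 s record
        series = resample_angles(t, np.sin(t), out_rate=100.0)
        assert abs(series.values.size - 1000) <= 1
        series.validate(100.0)

    def test_idempotent_at_same_rate(self):
        rng = np.random.default_rng(0)
        t = np.arange(4000) / 2000.0
        x = 20 * np.sin(2 * np.pi * t) + rng.normal(0, 0.3, t.size)
        first = resample_angles(t, x, out_rate=100.0)
        second = resample_angles(first.t, first.values, out_rate=100.0, fit_window=20)
        # re-fitting an already smooth 100 Hz series changes little
        assert np.max(np.abs(second.values - first.values[: second.values.size])) < 0.5

    def test_non_monotone_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            resample_angles(np.array([0.0, 0.2, 0.1]), np.zeros(3))


class TestMinMaxNormalization:
    def test_worked_example(self):
        xn, bounds = minmax_normalize(np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(xn, [0.0, 0.5, 1.0])
        assert bounds == (2.0, 6.0)

    def test_roundtrip_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 5, 200)
        xn, bounds = minmax_normalize(x)
        np.testing.assert_allclose(minmax_denormalize(xn, bounds), x, atol=1e-12)
        assert xn.min() == 0.0 and xn.max() == 1.0

    def test_supplied_bounds_clip(self):
        xn, _ = minmax_normalize(np.array([-1.0, 0.5, 2.0]), bounds=(0.0, 1.0))
        np.testing.assert_allclose(xn, [0.0, 0.5, 1.0])

    def test_constant_signal_rejected(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize(np.full(5, 3.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=hnp.arrays(
            float,
            st.integers(2, 50),
            elements=st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
        )
    )
    def test_roundtrip_property(self, x):
        if np.ptp(x) == 0:
            return
        xn, bounds = minmax_normalize(x)
        np.testing.assert_allclose(
            minmax_denormalize(xn, bounds), x, atol=1e-9 * max(1.0, np.max(np.abs(x)))
        )


class TestWaveletLowpass:
    def test_constant_unchanged(self):
        x = np.full(1024, 3.7)
        np.testing.assert_allclose(wavelet_lowpass(x), x, atol=1e-9)

    def test_energy_never_increases(self, rng):
        for n in (511, 1000, 1024, 3000):
            x = rng.standard_normal(n)
            y = wavelet_lowpass(x)
            assert np.sum(y**2) <= np.sum(x**2) * (1 + 1e-9)

    def test_projection_idempotent(self, rng):
        x = rng.standard_normal(1024)  # divisible by 2**6: exact projection
        once = wavelet_lowpass(x)
        twice = wavelet_lowpass(once)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_band_selectivity(self):
        """Tones inside the retained 0..fs/2^7 band survive; tones above
        it are removed (frozen from a dense frequency sweep)."""
        t = np.arange(3000) / 100.0
        inband = np.sin(2 * np.pi * 0.3 * t)
        rel = lambda y, x: np.sqrt(np.mean((y - x) ** 2) / np.mean(x**2))
        assert rel(wavelet_lowpass(inband), inband) < 0.05
        above = np.sin(2 * np.pi * 5.0 * t)
        assert np.sqrt(np.mean(wavelet_lowpass(above) ** 2)) < 0.05

    def test_noise_variance_reduced(self, rng):
        x = rng.standard_normal(2048)
        assert np.var(wavelet_lowpass(x)) < 0.1 * np.var(x)

    def test_level_autoreduction_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gaitgrnn.preprocessing"):
            wavelet_lowpass(np.ones(64), levels=6)
        assert any("reducing" in r.message for r in caplog.records)

    def test_empty_signal(self):
        assert wavelet_lowpass(np.empty(0)).size == 0


class TestWaveletDenoise:
    def test_signal_preserved(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)
        y = wavelet_denoise(x)
        assert np.sqrt(np.mean((y - x) ** 2) / np.mean(x**2)) < 0.01

    def test_wideband_noise_removed(self, rng):
        t = np.arange(2000) / 100.0
        clean = np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + rng.normal(0, 0.3, t.size)
        y = wavelet_denoise(noisy)
        assert np.sqrt(np.mean((y - clean) ** 2)) < 0.5 * np.sqrt(
            np.mean((noisy - clean) ** 2)
        )

    def test_spiky_signal_not_made_worse(self, rng):
        """Shrinkage attenuates (does not amplify) sparse spikes while
        the underlying tone is untouched."""
        t = np.arange(2000) / 100.0
        clean = np.sin(2 * np.pi * 1.0 * t)
        spiky = clean + rng.normal(0, 0.1, t.size)
        sites = rng.choice(2000, 15, replace=False)
        spiky[sites] += rng.uniform(2, 5, 15)
        y = wavelet_denoise(spiky)
        assert np.sqrt(np.mean((y - clean) ** 2)) < 0.98 * np.sqrt(
            np.mean((spiky - clean) ** 2)
        )

    def test_noiseless_input_untouched(self):
        x = np.zeros(512)
        np.testing.assert_allclose(wavelet_denoise(x), x, atol=1e-12)
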