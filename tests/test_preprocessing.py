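"""ΔF/F, bleach correction, Butterworth filtering and FWHM contracts."""

import numpy as np
import pytest

from dopamap.io import MovieStack, Trace
from dopamap.preprocessing import (
    BaselineSpec,
    compute_dff,
    correct_bleach,
    lowpass,
    profile_fwhm,
)
from dopamap.synthetic import SyntheticConfig, render_movie


class TestComputeDff:
    def test_constant_trace_is_zero_either_mode(self):
        tr = Trace(np.full(20, 37.0), 2.0)
        for spec in (BaselineSpec("prestim_mean", 5), BaselineSpec("trial_median")):
            assert np.allclose(compute_dff(tr, spec).values, 0.0)

    def test_formula_prestim_mean(self):
        tr = Trace(np.array([100.0, 100.0, 100.0, 150.0]), 1.0)
        out = compute_dff(tr, BaselineSpec("prestim_mean", 3))
        assert out.values[-1] == pytest.approx(0.5)

    def test_trial_median_hand_example(self):
        tr = Trace(np.array([100.0, 100.0, 100.0, 150.0, 125.0]), 1.0)
        out = compute_dff(tr, BaselineSpec("trial_median"))
        np.testing.assert_allclose(out.values, [0, 0, 0, 0.5, 0.25])

    def test_movie_uses_stim_frame_as_default_baseline_end(self):
        data = np.full((10, 4, 4), 200.0)
        data[5:] = 300.0
        movie = MovieStack(data, frame_rate=1.0, stim_frames=(5,))
        out = compute_dff(movie, BaselineSpec("prestim_mean"))
        assert np.allclose(out.data[:5], 0.0)
        assert np.allclose(out.data[5:], 0.5)

    def test_nonpositive_baseline_identifies_pixel(self):
        data = np.full((10, 4, 4), 100.0)
        data[:, 2, 3] = 0.0
        movie = MovieStack(data, frame_rate=1.0, stim_frames=(5,))
        with pytest.raises(ValueError, match=r"y=2, x=3"):
            compute_dff(movie, BaselineSpec("prestim_mean"))

    def test_roundtrip_inverts_exactly(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(50, 150, 30)
        tr = Trace(vals, 2.0)
        spec = BaselineSpec("prestim_mean", 10)
        f0 = vals[:10].mean()
        back = f0 * (1.0 + compute_dff(tr, spec).values)
        np.testing.assert_allclose(back, vals, rtol=1e-12)


class TestCorrectBleach:
    def test_pure_double_exponential_flattens_to_constant(self):
        t = np.arange(600) / 2.0
        y = 600.0 * np.exp(-t / 15.0) + 1400.0 * np.exp(-t / 80.0) + 50.0
        corrected, fit = correct_bleach(Trace(y, 2.0))
        assert fit.converged
        resid = np.ptp(corrected.values) / np.ptp(y)
        assert resid < 1e-6
        assert np.allclose(corrected.values, fit.c, rtol=1e-3)

    def test_generator_roundtrip_within_one_percent(self):
        cfg = SyntheticConfig(n_frames=600, height=16, width=16, frame_rate=2.0,
                              noise_sd=0.0, bleach=(0.3, 15.0, 0.7, 80.0), seed=1)
        movie = render_movie(np.zeros((600, 16, 16)), cfg)
        _, fit = correct_bleach(movie.mean_trace())
        est = sorted([(fit.tau1, fit.a1), (fit.tau2, fit.a2)])
        true = sorted([(15.0, 0.3 * cfg.f0_mean), (80.0, 0.7 * cfg.f0_mean)])
        for (tau_t, a_t), (tau_e, a_e) in zip(true, est):
            assert tau_e == pytest.approx(tau_t, rel=0.01)
            assert a_e == pytest.approx(a_t, rel=0.01)

    def test_constant_input_returned_unchanged(self, flat_trace):
        corrected, fit = correct_bleach(flat_trace)
        np.testing.assert_allclose(corrected.values, flat_trace.values, atol=1e-6)

    def test_transient_preserved_under_slow_bleach(self):
        # bleach tau >= 10x the transient width: peak changes < 5%
        fr = 5.0
        t = np.arange(1000) / fr
        bleach = 800.0 * np.exp(-t / 60.0) + 1200.0
        transient = 300.0 * np.exp(-((t - 100.0) ** 2) / (2 * 3.0**2))
        corrected, fit = correct_bleach(Trace(bleach + transient, fr))
        assert fit.converged
        base = np.median(corrected.values)
        peak_after = corrected.values[int(100 * fr)] - base
        assert peak_after == pytest.approx(300.0, rel=0.05)

    def test_idempotent_on_own_output(self):
        t = np.arange(600) / 2.0
        y = 600.0 * np.exp(-t / 15.0) + 1400.0 * np.exp(-t / 80.0) + 50.0
        once, _ = correct_bleach(Trace(y, 2.0))
        twice, _ = correct_bleach(once)
        scale = np.ptp(y)
        assert np.max(np.abs(twice.values - once.values)) / scale < 1e-6


class TestLowpass:
    def test_dc_gain_is_unity(self, flat_trace):
        out = lowpass(flat_trace, cutoff=0.5)
        np.testing.assert_allclose(out.values, flat_trace.values, rtol=1e-9)

    def test_gain_half_at_cutoff(self):
        fr, cut = 20.0, 1.0
        t = np.arange(0, 200, 1 / fr)
        sin = np.sin(2 * np.pi * cut * t)
        out = lowpass(Trace(sin, fr), cutoff=cut).values
        trim = slice(len(t) // 8, -len(t) // 8)
        gain = np.ptp(out[trim]) / np.ptp(sin[trim])
        assert gain == pytest.approx(0.5, rel=0.02)

    def test_gain_near_unity_deep_in_passband(self):
        fr, cut = 20.0, 1.0
        t = np.arange(0, 200, 1 / fr)
        sin = np.sin(2 * np.pi * cut / 10 * t)
        out = lowpass(Trace(sin, fr), cutoff=cut).values
        trim = slice(len(t) // 8, -len(t) // 8)
        assert np.ptp(out[trim]) / np.ptp(sin[trim]) >= 0.999

    def test_linearity(self):
        rng = np.random.default_rng(1)
        fr = 10.0
        x, y = rng.normal(size=300), rng.normal(size=300)
        fa = lowpass(Trace(2.0 * x + 3.0 * y, fr), cutoff=1.0).values
        fb = 2.0 * lowpass(Trace(x, fr), cutoff=1.0).values + 3.0 * lowpass(
            Trace(y, fr), cutoff=1.0
        ).values
        np.testing.assert_allclose(fa, fb, atol=1e-10)

    def test_zero_phase_does_not_shift_symmetric_pulse(self):
        fr = 10.0
        t = np.arange(600) / fr
        pulse = np.exp(-((t - 30.0) ** 2) / (2 * 2.0**2))
        out = lowpass(Trace(pulse, fr), cutoff=1.0).values
        assert abs(int(np.argmax(out)) - int(np.argmax(pulse))) <= 1

    def test_near_nyquist_default_valid_and_reject_above(self):
        tr = Trace(np.random.default_rng(0).normal(size=100), 1.47)
        lowpass(tr)  # 0.68 Hz below 0.735 Hz Nyquist: fine
        with pytest.raises(ValueError, match="0.735"):
            lowpass(tr, cutoff=0.8)


class TestProfileFwhm:
    def test_gaussian_closed_form(self):
        z = np.linspace(-6, 6, 2001)
        sigma = 1.3
        fwhm = profile_fwhm(z, np.exp(-(z**2) / (2 * sigma**2)))
        assert fwhm == pytest.approx(2 * sigma * np.sqrt(2 * np.log(2)), rel=0.01)

    def test_symmetric_triangle(self):
        b = 4.0
        z = np.linspace(-5, 5, 1001)
        prof = np.clip(1.0 - np.abs(z) / b, 0, None)
        assert profile_fwhm(z, prof) == pytest.approx(b, rel=1e-6)

    def test_rectangle_within_one_sample(self):
        z = np.linspace(0, 10, 201)  # dz = 0.05
        prof = ((z >= 3) & (z <= 7)).astype(float)
        assert profile_fwhm(z, prof) == pytest.approx(4.0, abs=0.06)

    def test_affine_intensity_invariance(self):
        z = np.linspace(-5, 5, 500)
        prof = np.exp(-(z**2) / 2.0)
        w0 = profile_fwhm(z, prof)
        assert profile_fwhm(z, 7.3 * prof + 11.0) == pytest.approx(w0, rel=1e-12)

    def test_truncated_profile_rejected(self):
        z = np.linspace(0, 2, 100)
        prof = np.exp(-((z - 1.9) ** 2) / 2.0)  # peak near edge, right side truncated
        with pytest.raises(ValueError):
            profile_fwhm(z, prof)
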