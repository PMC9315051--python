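import numpy as np
import pytest
from scipy import integrate

import pushpulse as pp
from pushpulse.saturation_physics import _super_lorentzian_integral


class TestGaussianSubPulse:
    def test_peak_normalized_and_symmetric(self, gauss_wave):
        assert np.max(np.abs(gauss_wave.samples)) == pytest.approx(1.0, abs=0)
        assert np.allclose(gauss_wave.samples, gauss_wave.samples[::-1])
        assert gauss_wave.duration == pytest.approx(4e-3)

    def test_spectral_fwhm_matches_tbp(self, gauss_wave):
        # FWHM bandwidth should be tbp/tau = 567.5 Hz; truncating the
        # envelope at +-tau/2 broadens the measured FWHM by a few per mil
        n_pad = 1 << 18
        spec = np.abs(np.fft.rfft(gauss_wave.samples.real, n_pad))
        freqs = np.fft.rfftfreq(n_pad, gauss_wave.dt)
        half = spec[0] / 2.0
        f_half = freqs[np.argmax(spec < half)]
        assert 2.0 * f_half == pytest.approx(2.27 / 4e-3, rel=1e-2)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pp.make_gaussian_subpulse(2.27, 4e-3, 5e-3)  # dt >= tau
        with pytest.raises(ValueError):
            pp.make_gaussian_subpulse(-1.0, 4e-3, 1e-5)


class TestNormalizedMeanSquare:
    def test_rect_closed_form(self):
        wave = pp.make_rect_subpulse(4e-3, 10e-6)
        assert pp.normalized_mean_square(wave, 22e-3) == pytest.approx(4.0 / 22.0)

    def test_long_tr_limit(self):
        wave = pp.make_rect_subpulse(4e-3, 10e-6)
        assert pp.normalized_mean_square(wave, 1e6) < 1e-8

    def test_tr_shorter_than_pulse_rejected(self, gauss_wave):
        with pytest.raises(ValueError):
            pp.normalized_mean_square(gauss_wave, 3e-3)

    def test_matches_fine_quadrature(self, gauss_wave):
        # independent oracle: adaptive quadrature of the analytic truncated
        # Gaussian, with the same peak-sample renormalization computed
        # analytically from (tbp, tau, dt)
        sigma = gauss_wave.shape_meta["sigma_t"]
        tau, dt = 4e-3, 10e-6
        renorm = np.exp((dt / 2.0) ** 2 / (2.0 * sigma**2))
        integral, _ = integrate.quad(
            lambda t: (renorm * np.exp(-((t - tau / 2) ** 2) / (2 * sigma**2))) ** 2,
            0.0,
            tau,
            limit=200,
        )
        oracle = integral / 22e-3
        value = pp.normalized_mean_square(gauss_wave, 22e-3)
        assert value == pytest.approx(oracle, rel=1e-6)

    def test_discretization_convergence(self):
        coarse = pp.make_gaussian_subpulse(2.27, 4e-3, 10e-6)
        fine = pp.make_gaussian_subpulse(2.27, 4e-3, 5e-6)
        a = pp.normalized_mean_square(coarse, 22e-3)
        b = pp.normalized_mean_square(fine, 22e-3)
        assert abs(a - b) / a < 1e-4


class TestComputeB1rms:
    def test_single_channel_closed_form(self, uniform_single_channel_setup):
        wave = pp.make_rect_subpulse(4e-3, 10e-6)
        spec = pp.SaturationPulseSpec(waveform=wave, n_subpulses=1, tr=22e-3)
        w = pp.WeightSet(np.array([[100.0 + 0j]]))
        b1 = pp.compute_b1rms(uniform_single_channel_setup, spec, w)
        assert np.allclose(
            b1[uniform_single_channel_setup.mask], 100.0 * np.sqrt(4.0 / 22.0)
        )

    def test_zero_weights_zero_map(self, scenario2d):
        w = pp.WeightSet(np.zeros((1, 8)))
        b1 = pp.compute_b1rms(scenario2d.setup, scenario2d.spec, w)
        assert not b1.any()

    def test_matches_time_domain_synthesis(self, scenario2d, gauss_wave):
        # brute force: synthesize B1+(t) over the whole TR and take the RMS
        spec = pp.SaturationPulseSpec(
            waveform=gauss_wave, n_subpulses=3, offset_hz=2000.0, tr=22e-3
        )
        rng = np.random.default_rng(5)
        w = pp.WeightSet(
            10 * (rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8)))
        )
        b1 = pp.compute_b1rms(scenario2d.setup, spec, w)
        vox = np.argwhere(scenario2d.setup.mask)
        env, dt, tr = gauss_wave.samples, gauss_wave.dt, 22e-3
        silence = np.zeros(int(round(tr / dt)) - 3 * env.size)
        for iy, ix in vox[rng.choice(len(vox), 25, replace=False)]:
            s = scenario2d.setup.sensitivities[:, iy, ix]
            series = np.concatenate([(s @ w.w[p]) * env for p in range(3)] + [silence])
            rms = np.sqrt(np.sum(np.abs(series) ** 2) * dt / tr)
            assert b1[iy, ix] == pytest.approx(rms, rel=1e-9)

    def test_shape_mismatch_rejected(self, scenario2d):
        with pytest.raises(ValueError):
            pp.compute_b1rms(
                scenario2d.setup, scenario2d.spec, pp.WeightSet(np.ones((2, 8)))
            )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariances(self, scenario2d, gauss_wave, seed):
        """Permutation of sub-pulses, per-sub-pulse global phase, scalar
        scaling, and zero-padded sub-pulses all act as expected."""
        rng = np.random.default_rng(seed)
        w = 20 * (rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8)))
        spec3 = pp.SaturationPulseSpec(waveform=gauss_wave, n_subpulses=3, tr=22e-3)
        spec4 = pp.SaturationPulseSpec(waveform=gauss_wave, n_subpulses=4, tr=22e-3)
        base = pp.compute_b1rms(scenario2d.setup, spec3, pp.WeightSet(w))
        perm = pp.compute_b1rms(scenario2d.setup, spec3, pp.WeightSet(w[[2, 0, 1]]))
        assert np.allclose(perm, base, rtol=1e-13, atol=0)
        phased = w.copy()
        phased[1] *= np.exp(1j * rng.uniform(0, 2 * np.pi))
        assert np.allclose(
            pp.compute_b1rms(scenario2d.setup, spec3, pp.WeightSet(phased)), base
        )
        scaled = pp.compute_b1rms(scenario2d.setup, spec3, pp.WeightSet(-2.5 * w))
        assert np.allclose(scaled, 2.5 * base)
        padded = np.vstack([w, np.zeros((1, 8))])
        assert np.allclose(
            pp.compute_b1rms(scenario2d.setup, spec4, pp.WeightSet(padded)), base
        )


class TestLineshapes:
    def test_lorentzian_peak(self):
        ls = pp.Lineshape(kind="lorentzian", t2s=9.6e-6, chemical_shift_hz=0.0)
        assert pp.lineshape_value(ls, 0.0) == pytest.approx(9.6e-6 / np.pi)

    def test_gaussian_unit_area_over_angular_frequency(self):
        ls = pp.Lineshape(kind="gaussian", t2s=9.6e-6, chemical_shift_hz=0.0)
        area, _ = integrate.quad(
            lambda d: pp.lineshape_value(ls, d), -1e6, 1e6, limit=500
        )
        assert 2.0 * np.pi * area == pytest.approx(1.0, rel=1e-6)

    def test_super_lorentzian_matches_dense_quadrature(self):
        ls = pp.Lineshape(kind="super_lorentzian", t2s=9.6e-6, chemical_shift_hz=-773.0)
        g = pp.lineshape_value(ls, 2000.0)  # effective offset 2773 Hz
        t2s, d = 9.6e-6, 2773.0
        theta = np.linspace(0.0, np.pi / 2, 2_000_001)
        c = 3.0 * np.cos(theta) ** 2 - 1.0
        safe = np.where(c == 0.0, 1.0, c)
        integrand = np.where(
            np.abs(c) < 1e-12,
            0.0,
            np.sin(theta) * (t2s / np.abs(safe)) * np.exp(-2 * (2 * np.pi * d * t2s / safe) ** 2),
        )
        dense = np.sqrt(2.0 / np.pi) * np.trapezoid(integrand, theta)
        assert g == pytest.approx(dense, rel=1e-6)

    def test_near_resonance_extrapolation_flagged(self):
        ls = pp.Lineshape(kind="super_lorentzian", t2s=9.6e-6, chemical_shift_hz=0.0)
        g, meta = pp.lineshape_value(ls, 500.0, return_meta=True)
        assert meta["extrapolated"]
        assert g > 0
        _, meta2 = pp.lineshape_value(ls, 1500.0, return_meta=True)
        assert not meta2["extrapolated"]

    @pytest.mark.parametrize("kind", ["super_lorentzian", "gaussian", "lorentzian"])
    def test_non_negative(self, kind):
        ls = pp.Lineshape(kind=kind, t2s=9.6e-6, chemical_shift_hz=-773.0)
        for d in (-5000.0, -773.0, 0.0, 1500.0, 2000.0, 20000.0):
            assert pp.lineshape_value(ls, d) >= 0


class TestMeanSaturationRate:
    def test_zero_field(self):
        assert pp.mean_saturation_rate(0.0, pp.Lineshape(), 2000.0) == 0.0

    def test_quadratic_law(self):
        ls = pp.Lineshape()
        w1 = pp.mean_saturation_rate(1.0, ls, 2000.0)
        w2 = pp.mean_saturation_rate(2.0, ls, 2000.0)
        assert w2 == pytest.approx(4.0 * w1, rel=1e-12)

    def test_composition_with_lineshape_oracle(self):
        ls = pp.Lineshape(kind="super_lorentzian", t2s=9.6e-6, chemical_shift_hz=-773.0)
        g = _super_lorentzian_integral(2773.0, 9.6e-6)
        w = pp.mean_saturation_rate(1.0, ls, 2000.0)
        assert w == pytest.approx(np.pi * 267.522**2 * g, rel=1e-10)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            pp.mean_saturation_rate(-0.1, pp.Lineshape(), 2000.0)
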