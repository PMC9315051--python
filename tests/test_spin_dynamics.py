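import numpy as np
import pytest
from scipy.linalg import expm

import pushpulse as pp
from pushpulse.constants import GAMMA_RAD_PER_S_PER_UT as GAMMA


class TestHardPulsePropagate:
    def test_zero_rf_zero_offset_identity(self):
        r = pp.hard_pulse_propagate(np.zeros(50, complex), 0.0, 1e-5)
        assert np.allclose(r, np.eye(3), atol=1e-15)

    def test_on_resonance_90_degree_pulse(self):
        tau = (np.pi / 2) / GAMMA  # gamma * B1 * tau = pi/2 at B1 = 1 uT
        n = 1000
        r = pp.hard_pulse_propagate(np.ones(n, complex), 0.0, tau / n)
        flip = np.degrees(np.arccos(np.clip(r[2, 2], -1, 1)))
        assert flip == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_stepwise_expm_oracle(self, seed):
        rng = np.random.default_rng(seed)
        b1 = rng.standard_normal(30) + 1j * rng.standard_normal(30)
        dbz, dt = 150.0, 1e-5
        r = pp.hard_pulse_propagate(b1, dbz, dt)
        oracle = np.eye(3)
        wz = 2 * np.pi * dbz
        for b in b1:
            a = np.array(
                [
                    [0.0, wz, -GAMMA * b.imag],
                    [-wz, 0.0, GAMMA * b.real],
                    [GAMMA * b.imag, -GAMMA * b.real, 0.0],
                ]
            )
            oracle = expm(a * dt) @ oracle
        assert np.allclose(r, oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_proper_rotation(self, seed):
        rng = np.random.default_rng(seed)
        b1 = 5 * (rng.standard_normal(200) + 1j * rng.standard_normal(200))
        r = pp.hard_pulse_propagate(b1, rng.uniform(-500, 500), 1e-5)
        assert np.abs(r @ r.T - np.eye(3)).max() < 1e-10
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)


class TestFlipAngleMap:
    def test_zero_weights_zero_map(self, scenario2d):
        w = pp.WeightSet(np.zeros((1, 8)))
        fmap = pp.flip_angle_map(scenario2d.setup, scenario2d.spec, w)
        assert np.allclose(fmap, 0.0)

    def test_single_voxel_fine_step_oracle(self, gauss_wave):
        setup = pp.TransmitSetup(
            sensitivities=np.full((1, 1, 1), 0.1 + 0.05j),
            mask=np.ones((1, 1), bool),
            voxel_size_mm=(4.0, 4.0),
            db0_hz=np.full((1, 1), 120.0),
        )
        spec = pp.SaturationPulseSpec(
            waveform=gauss_wave, n_subpulses=1, offset_hz=2000.0, tr=22e-3
        )
        w = pp.WeightSet(np.array([[20.0 + 5.0j]]))
        fmap = pp.flip_angle_map(setup, spec, w)
        # brute-force Bloch integration of the same piecewise-constant
        # envelope at 10x finer time steps
        field = setup.sensitivities[0, 0, 0] * w.w[0, 0]
        env_fine = np.repeat(gauss_wave.samples, 10)
        r = pp.hard_pulse_propagate(field * env_fine, 120.0, gauss_wave.dt / 10)
        oracle = np.degrees(np.arccos(np.clip(r[2, 2], -1, 1)))
        assert fmap[0, 0] == pytest.approx(oracle, abs=1e-4)

    def test_blips_change_flip_but_not_b1rms(self, scenario2d, gauss_wave):
        rng = np.random.default_rng(7)
        w = pp.WeightSet(
            15 * (rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8)))
        )
        blip = pp.GradientBlip(duration_s=100e-6, phase_rolls=(2.0, 2.0))
        spec0 = pp.SaturationPulseSpec(
            waveform=gauss_wave, n_subpulses=3, offset_hz=2000.0, tr=22e-3
        )
        spec1 = pp.SaturationPulseSpec(
            waveform=gauss_wave, n_subpulses=3, offset_hz=2000.0, tr=22e-3,
            inter_pulse_blips=[blip, blip],
        )
        blip2 = pp.GradientBlip(duration_s=100e-6, phase_rolls=(4.0, 4.0))
        spec2 = pp.SaturationPulseSpec(
            waveform=gauss_wave, n_subpulses=3, offset_hz=2000.0, tr=22e-3,
            inter_pulse_blips=[blip2, blip2],
        )
        setup = scenario2d.setup
        b0 = pp.compute_b1rms(setup, spec0, w)
        b1 = pp.compute_b1rms(setup, spec1, w)
        assert np.array_equal(b0, b1)  # bit-identical: blips never enter
        f0 = pp.flip_angle_map(setup, spec0, w)
        f1 = pp.flip_angle_map(setup, spec1, w)
        f2 = pp.flip_angle_map(setup, spec2, w)
        m = setup.mask
        assert np.abs(f1 - f0)[m].max() > 0.1
        assert np.abs(f2 - f1)[m].max() > 0.1  # doubling the roll changes it again


class TestSemisolidDecay:
    def test_limits(self):
        assert pp.semisolid_decay(0.0, 5e-3) == 1.0
        assert pp.semisolid_decay(3.0, 0.0) == 1.0

    def test_composition_with_saturation_rate(self, wm_tissue):
        w = pp.mean_saturation_rate(1.0, wm_tissue.lineshape, 2000.0)
        assert pp.semisolid_decay(w, 22e-3) == pytest.approx(np.exp(-w * 22e-3))


class TestSpgrSteadyState:
    def test_ernst_formula_limit(self):
        tissue = pp.TissueParams(r1f=0.4, t2f=0.06, f=0.0, k=0.0, r1s=1.85)
        seq = pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0)
        s = pp.spgr_mt_steady_state(tissue, seq, 0.0)
        a, e1 = np.deg2rad(5.0), np.exp(-0.4 * 22e-3)
        ernst = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
        assert s == pytest.approx(ernst, rel=1e-10)

    def test_zero_flip_angle_gives_zero_signal(self, wm_tissue):
        seq = pp.SequenceSpec(tr=22e-3, alpha_exc_deg=0.0)
        assert pp.spgr_mt_steady_state(wm_tissue, seq, 1.0) == 0.0

    def test_fixed_point_matches_long_run_iteration(self, wm_tissue):
        seq = pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0)
        w = pp.mean_saturation_rate(1.0, wm_tissue.lineshape, 2000.0)
        fp = pp.spgr_mt_steady_state(wm_tissue, seq, w)
        it = pp.iterate_spgr_mt(wm_tissue, seq, w, 5.0, 100_000)
        assert fp == pytest.approx(it, rel=1e-8)

    def test_discrete_event_variant_close_to_cw_at_short_tr(self, wm_tissue):
        w = pp.mean_saturation_rate(1.0, wm_tissue.lineshape, 2000.0)
        cw = pp.spgr_mt_steady_state(
            wm_tissue, pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0), w
        )
        disc = pp.spgr_mt_steady_state(
            wm_tissue,
            pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0, saturation_mode="discrete"),
            w,
        )
        assert disc == pytest.approx(cw, rel=2e-2)


class TestSimulateMtr:
    def _sequence(self, scenario, nsp):
        spec = pp.SaturationPulseSpec(
            waveform=scenario.spec.waveform,
            n_subpulses=nsp,
            offset_hz=2000.0,
            tr=22e-3,
        )
        return pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0, saturation=spec)

    def test_zero_weights_zero_mtr(self, scenario2d, wm_tissue):
        seq = self._sequence(scenario2d, 1)
        res = pp.simulate_mtr(
            scenario2d.setup, wm_tissue, seq, pp.WeightSet(np.zeros((1, 8)))
        )
        assert np.allclose(res.mtr, 0.0)

    def test_no_semisolid_pool_no_contrast(self, scenario2d):
        tissue = pp.TissueParams(r1f=0.4, t2f=0.06, f=0.0, k=0.0, r1s=1.85)
        seq = self._sequence(scenario2d, 1)
        w = pp.WeightSet(30 * np.exp(-1j * 2 * np.pi * np.arange(8) / 8)[None, :])
        res = pp.simulate_mtr(scenario2d.setup, tissue, seq, w)
        assert np.abs(res.mtr).max() < 1e-10

    def test_uniform_b1rms_gives_uniform_mtr(
        self, uniform_single_channel_setup, wm_tissue, gauss_wave
    ):
        spec = pp.SaturationPulseSpec(waveform=gauss_wave, n_subpulses=1, tr=22e-3)
        seq = pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0, saturation=spec)
        res = pp.simulate_mtr(
            uniform_single_channel_setup, wm_tissue, seq,
            pp.WeightSet(np.array([[4.0 + 0j]])),
        )
        inside = res.mtr[uniform_single_channel_setup.mask]
        assert inside.std() == pytest.approx(0.0, abs=1e-12)
        assert 0 < inside.mean() < 100

    def test_mtr_monotone_in_beta(
        self, uniform_single_channel_setup, wm_tissue, gauss_wave
    ):
        """MTR grows monotonically with target B1rms on white matter."""
        spec = pp.SaturationPulseSpec(waveform=gauss_wave, n_subpulses=1, tr=22e-3)
        seq = pp.SequenceSpec(tr=22e-3, alpha_exc_deg=5.0, saturation=spec)
        duty = pp.normalized_mean_square(gauss_wave, 22e-3)
        last = -1.0
        for beta in np.linspace(0.0, 2.0, 11):
            w = pp.WeightSet(np.array([[beta / np.sqrt(duty) + 0j]]))
            res = pp.simulate_mtr(uniform_single_channel_setup, wm_tissue, seq, w)
            val = res.mtr[uniform_single_channel_setup.mask].mean()
            assert val >= last - 1e-12
            last = val

    def test_mtr_within_physical_range(self, scenario2d, wm_tissue):
        seq = self._sequence(scenario2d, 1)
        w = pp.WeightSet(40 * np.exp(-1j * 2 * np.pi * np.arange(8) / 8)[None, :])
        res = pp.simulate_mtr(scenario2d.setup, wm_tissue, seq, w)
        m = scenario2d.setup.mask
        assert res.mtr[m].min() >= 0.0
        assert res.mtr[m].max() <= 100.0
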