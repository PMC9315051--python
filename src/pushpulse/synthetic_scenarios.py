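"""Reproducible end-to-end scenarios: coil + VOPs + tissue + sequence.

A :class:`Scenario` binds every component the pipeline needs, fully
specified by (name, seed) with no hidden state.  The 2D scenario mirrors
the published simulation conditions — 8 channels, a single axial slice,
Gaussian sub-pulses (TBP 2.27, 4 ms, 10 us raster) at 2 kHz offset, TR
22 ms, white-matter tissue, first-level limits {20 W/kg, 207 V, 24 W} —
on a 64 x 64 grid sized so a full beta sweep runs in minutes on one CPU
(the optimizer's mathematics does not need the acquisition-resolution
matrix).  The 3D scenario adds superior/inferior sensitivity falloff
from mid-volume ring elements, reproducing the z-axis limitation of
circumferential coils.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coil_fields import TransmitSetup, generate_synthetic_setup
from .push_design import DesignProblem
from .rf_constraints import HardwareLimits, VOPSet, make_synthetic_vops
from .saturation_physics import (
    SaturationPulseSpec,
    make_gaussian_subpulse,
    normalized_mean_square,
)
from .spin_dynamics import SequenceSpec, TissueParams, white_matter


@dataclass
class Scenario:
    name: str
    seed: int
    setup: TransmitSetup
    vops: VOPSet
    tissue: TissueParams
    spec: SaturationPulseSpec
    limits: HardwareLimits

    def __post_init__(self) -> None:
        if self.vops.n_channels != self.setup.n_channels:
            raise ValueError("VOP channel count does not match the coil")

    def sequence(self, alpha_exc_deg: float = 5.0) -> SequenceSpec:
        return SequenceSpec(
            tr=self.spec.tr, alpha_exc_deg=alpha_exc_deg, saturation=self.spec
        )

    def problem(self, beta_ut: float, region=None) -> DesignProblem:
        return DesignProblem(
            setup=self.setup,
            spec=self.spec,
            beta_ut=beta_ut,
            vops=self.vops,
            limits=self.limits,
            region=region,
        )


def _default_pulse(n_subpulses: int = 1) -> SaturationPulseSpec:
    wave = make_gaussian_subpulse(tbp=2.27, tau=4e-3, dt=10e-6)
    return SaturationPulseSpec(
        waveform=wave, n_subpulses=n_subpulses, offset_hz=2000.0, tr=22e-3
    )


def _assemble(name: str, setup: TransmitSetup, seed: int) -> Scenario:
    spec = _default_pulse()
    duty = normalized_mean_square(spec.waveform, spec.tr)
    vops = make_synthetic_vops(
        setup,
        n_vop=8,
        seed=seed,
        target_sar=10.0,
        reference_b1rms=1.0,
        duty=duty,
        sar_limit=20.0,
    )
    return Scenario(
        name=name,
        seed=seed,
        setup=setup,
        vops=vops,
        tissue=white_matter(),
        spec=spec,
        limits=HardwareLimits(v_max=207.0, p_max=24.0, impedance=50.0),
    )


def paper_2d_scenario(seed: int = 0) -> Scenario:
    """8-channel, 64 x 64 single-axial-slice scenario (240 mm FOV)."""
    setup = generate_synthetic_setup(
        n_channels=8, grid_shape=(64, 64), fov_mm=240.0, seed=seed
    )
    return _assemble("paper2d", setup, seed)


def paper_3d_scenario(seed: int = 0) -> Scenario:
    """8-channel, 32 x 48 x 48 volume scenario with z-axis falloff."""
    setup = generate_synthetic_setup(
        n_channels=8,
        grid_shape=(32, 48, 48),
        fov_mm=(192.0, 240.0, 240.0),
        seed=seed,
    )
    return _assemble("paper3d", setup, seed)


SCENARIOS = {"paper2d": paper_2d_scenario, "paper3d": paper_3d_scenario}


def get_scenario(name: str, seed: int = 0) -> Scenario:
    try:
        return SCENARIOS[name](seed)
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
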