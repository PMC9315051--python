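"""YAML configuration for the command-line tools.

A config file assembles a design problem from either a named synthetic
scenario or on-disk maps.  Recognized keys (all optional, defaults in
parentheses):

.. code-block:: yaml

    scenario: paper2d          # or paper3d; omit when loading files
    coil:
      n_channels: 8
      seed: 0
      slice_index: null        # 2D design on one axial slice of a 3D setup
      setup_dir: null          # directory written by save_setup
    pulse:
      tbp: 2.27
      tau_ms: 4.0
      dt_us: 10.0
      offset_hz: 2000.0
      n_subpulses: 2
    seq:
      tr_ms: 22.0
      alpha_exc_deg: 5.0
    lineshape:
      kind: super_lorentzian
      t2s_us: 9.6
      shift_hz: -773.0
    limits:
      sar_10g: 20.0
      v_max: 207.0
      p_max_per_channel: 24.0
      impedance_ohm: 50.0
    design:
      beta_ut: 1.0
      n_subpulses: 2
      n_starts: 10
      seed: 0
      region: "3d"             # or an axial slice index
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .coil_fields import load_setup_dir
from .push_design import DesignProblem
from .rf_constraints import HardwareLimits, load_vops, make_synthetic_vops
from .saturation_physics import (
    Lineshape,
    SaturationPulseSpec,
    make_gaussian_subpulse,
    normalized_mean_square,
)
from .spin_dynamics import TissueParams, white_matter
from .synthetic_scenarios import Scenario, get_scenario


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def pulse_from_config(cfg: dict) -> SaturationPulseSpec:
    p = cfg.get("pulse", {})
    s = cfg.get("seq", {})
    wave = make_gaussian_subpulse(
        tbp=float(p.get("tbp", 2.27)),
        tau=float(p.get("tau_ms", 4.0)) * 1e-3,
        dt=float(p.get("dt_us", 10.0)) * 1e-6,
    )
    return SaturationPulseSpec(
        waveform=wave,
        n_subpulses=int(p.get("n_subpulses", 1)),
        offset_hz=float(p.get("offset_hz", 2000.0)),
        tr=float(s.get("tr_ms", 22.0)) * 1e-3,
    )


def limits_from_config(cfg: dict) -> HardwareLimits:
    lim = cfg.get("limits", {})
    return HardwareLimits(
        v_max=float(lim.get("v_max", 207.0)),
        p_max=float(lim.get("p_max_per_channel", 24.0)),
        impedance=float(lim.get("impedance_ohm", 50.0)),
    )


def tissue_from_config(cfg: dict) -> TissueParams:
    tissue = white_matter()
    ls = cfg.get("lineshape")
    if ls:
        tissue.lineshape = Lineshape(
            kind=ls.get("kind", "super_lorentzian"),
            t2s=float(ls.get("t2s_us", 9.6)) * 1e-6,
            chemical_shift_hz=float(ls.get("shift_hz", -773.0)),
        )
    return tissue


def scenario_from_config(cfg: dict, seed: int | None = None) -> Scenario:
    """Build a scenario from config: named synthetic or file-backed."""
    coil = cfg.get("coil", {})
    eff_seed = seed if seed is not None else int(coil.get("seed", 0))
    if cfg.get("scenario"):
        scen = get_scenario(cfg["scenario"], seed=eff_seed)
    else:
        setup = load_setup_dir(coil["setup_dir"])
        spec = pulse_from_config(cfg)
        vop_file = cfg.get("vops", {}).get("file")
        if vop_file:
            vops = load_vops(vop_file)
        else:
            vops = make_synthetic_vops(
                setup,
                seed=eff_seed,
                duty=normalized_mean_square(spec.waveform, spec.tr),
                sar_limit=float(cfg.get("limits", {}).get("sar_10g", 20.0)),
            )
        scen = Scenario(
            name="config",
            seed=eff_seed,
            setup=setup,
            vops=vops,
            tissue=tissue_from_config(cfg),
            spec=spec,
            limits=limits_from_config(cfg),
        )
    # overrides that apply to named scenarios too
    if "pulse" in cfg or "seq" in cfg:
        scen.spec = pulse_from_config(cfg)
    if "limits" in cfg:
        scen.limits = limits_from_config(cfg)
    if "lineshape" in cfg:
        scen.tissue = tissue_from_config(cfg)
    return scen


def problem_from_config(cfg: dict, seed: int | None = None) -> DesignProblem:
    scen = scenario_from_config(cfg, seed=seed)
    design = cfg.get("design", {})
    setup = scen.setup
    region = None
    reg_key = design.get("region", cfg.get("coil", {}).get("slice_index"))
    if reg_key is not None and reg_key != "3d" and setup.mask.ndim == 3:
        region = np.zeros_like(setup.mask)
        region[int(reg_key)] = setup.mask[int(reg_key)]
    return DesignProblem(
        setup=setup,
        spec=scen.spec,
        beta_ut=float(design.get("beta_ut", 1.0)),
        vops=scen.vops,
        limits=scen.limits,
        region=region,
    )
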