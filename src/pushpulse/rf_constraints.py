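"""Local-SAR (VOP), per-channel power and peak-voltage constraints.

Local SAR is supervised through virtual observation points (VOPs): a
small set of Hermitian positive-semidefinite channel-space matrices Q_v
whose quadratic forms upper-bound the 10g-averaged SAR anywhere in the
body.  With the TR duty factor ``bbar2`` of the shared envelope, the
TR-averaged SAR at VOP v for a weight set w is

    SAR_v = bbar2 * sum_p  w_p^H Q_v w_p      [W/kg]

and the TR-averaged power into channel j (reference impedance Z) is

    P_j = bbar2 / Z * sum_p |w_jp|^2          [W].

Real systems ship vendor-computed VOPs; :func:`make_synthetic_vops`
builds surrogate ones calibrated so a stated CP-mode reference drive
produces a stated worst-VOP SAR, which fixes the overall scale in a
physically meaningful way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coil_fields import TransmitSetup
from .saturation_physics import SubPulseWaveform, WeightSet, normalized_mean_square


@dataclass
class VOPSet:
    """Hermitian PSD matrices Q_v (NVOP, Nch, Nch), W/kg per V^2 of drive
    after multiplication by the waveform duty factor."""

    matrices: np.ndarray
    sar_limit: float = 20.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=complex)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("VOP matrices must have shape (NVOP, Nch, Nch)")
        if self.matrices.shape[0] < 1:
            raise ValueError("need at least one VOP")
        herm_err = np.max(
            np.abs(self.matrices - np.conj(np.swapaxes(self.matrices, 1, 2)))
        )
        if herm_err > 1e-10 * max(1.0, np.max(np.abs(self.matrices))):
            raise ValueError("VOP matrices must be Hermitian")
        for q in self.matrices:
            ev = np.linalg.eigvalsh(q)
            if ev.min() < -1e-10 * max(ev.max(), 1.0):
                raise ValueError("VOP matrices must be positive semidefinite")
        if self.sar_limit <= 0:
            raise ValueError("SAR limit must be positive")

    @property
    def n_vop(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


@dataclass
class HardwareLimits:
    """Peak voltage per sub-pulse/channel, TR-averaged power per channel."""

    v_max: float = 207.0
    p_max: float = 24.0
    impedance: float = 50.0

    def __post_init__(self) -> None:
        if min(self.v_max, self.p_max, self.impedance) <= 0:
            raise ValueError("all hardware limits must be positive")


def sar_per_vop(weights: WeightSet, vops: VOPSet, duty: float) -> np.ndarray:
    """TR-averaged SAR at each VOP (W/kg); duty is bbar2 over the TR."""
    if weights.n_channels != vops.n_channels:
        raise ValueError(
            f"weights have {weights.n_channels} channels, VOPs expect "
            f"{vops.n_channels}"
        )
    # sum_p w_p^H Q_v w_p for all v at once
    qw = np.einsum("vjk,pk->vpj", vops.matrices, weights.w)
    sar = duty * np.real(np.einsum("pj,vpj->v", np.conj(weights.w), qw))
    return np.maximum(sar, 0.0)


def channel_power(
    weights: WeightSet, waveform: SubPulseWaveform, tr: float, impedance: float = 50.0
) -> np.ndarray:
    """TR-averaged forward power per channel in W."""
    if tr < weights.n_subpulses * waveform.duration:
        raise ValueError("TR shorter than the sub-pulse train")
    duty = normalized_mean_square(waveform, tr)
    return duty * np.sum(np.abs(weights.w) ** 2, axis=0) / impedance


@dataclass
class ConstraintReport:
    """Per-constraint values, margins (limit minus value) and feasibility."""

    sar: np.ndarray
    sar_limit: float
    power: np.ndarray
    p_max: float
    peak_voltage: float
    v_max: float
    feasible: bool
    worst_fractional_violation: float
    active: dict = field(default_factory=dict)

    @property
    def sar_margin(self) -> float:
        return float(self.sar_limit - self.sar.max())

    @property
    def power_margin(self) -> float:
        return float(self.p_max - self.power.max())

    @property
    def voltage_margin(self) -> float:
        return float(self.v_max - self.peak_voltage)

    def binding(self, rel_tol: float = 1e-3) -> list[str]:
        """Names of constraints within rel_tol (relative) of their limit."""
        out = []
        if self.sar.max() >= self.sar_limit * (1.0 - rel_tol):
            out.append("sar")
        if self.power.max() >= self.p_max * (1.0 - rel_tol):
            out.append("power")
        if self.peak_voltage >= self.v_max * (1.0 - rel_tol):
            out.append("voltage")
        return out


def check_feasible(
    weights: WeightSet,
    vops: VOPSet,
    limits: HardwareLimits,
    waveform: SubPulseWaveform,
    tr: float,
    rel_tol: float = 1e-6,
) -> ConstraintReport:
    """Audit a weight set against SAR, power and voltage limits.

    Infeasibility is reported, never raised: the report carries each
    constraint's value, margin, and the worst fractional violation.
    """
    duty = normalized_mean_square(waveform, tr)
    sar = sar_per_vop(weights, vops, duty)
    power = channel_power(weights, waveform, tr, limits.impedance)
    vpk = float(np.max(np.abs(weights.w))) if weights.w.size else 0.0
    fracs = {
        "sar": sar.max() / vops.sar_limit - 1.0,
        "power": power.max() / limits.p_max - 1.0,
        "voltage": vpk / limits.v_max - 1.0,
    }
    worst = max(fracs.values())
    return ConstraintReport(
        sar=sar,
        sar_limit=vops.sar_limit,
        power=power,
        p_max=limits.p_max,
        peak_voltage=vpk,
        v_max=limits.v_max,
        feasible=bool(worst <= rel_tol),
        worst_fractional_violation=float(worst),
        active={k: v >= -1e-3 for k, v in fracs.items()},
    )


def max_feasible_scale(
    weights: WeightSet,
    vops: VOPSet,
    limits: HardwareLimits,
    waveform: SubPulseWaveform,
    tr: float,
) -> float:
    """Largest c such that c * weights satisfies every constraint.

    SAR and power scale with c^2, peak voltage with c, so the bound has a
    closed form.  Returns inf for an all-zero weight set.
    """
    duty = normalized_mean_square(waveform, tr)
    sar = sar_per_vop(weights, vops, duty).max()
    power = channel_power(weights, waveform, tr, limits.impedance).max()
    vpk = float(np.max(np.abs(weights.w)))
    scales = []
    if sar > 0:
        scales.append(np.sqrt(vops.sar_limit / sar))
    if power > 0:
        scales.append(np.sqrt(limits.p_max / power))
    if vpk > 0:
        scales.append(limits.v_max / vpk)
    return float(min(scales)) if scales else float("inf")


def make_synthetic_vops(
    setup: TransmitSetup,
    n_vop: int = 8,
    seed: int = 0,
    target_sar: float = 10.0,
    reference_b1rms: float = 1.0,
    duty: float = 0.053,
    sar_limit: float = 20.0,
) -> VOPSet:
    """Build random Hermitian PSD VOP matrices with a physical calibration.

    Each Q_v is a random rank-deficient Gram matrix (a local E-field
    surrogate) plus a dominant diagonal load, mirroring how VOP
    compression algorithms add a global power-overestimation term to
    guarantee the upper bound.  All matrices are then rescaled together
    so that a single-sub-pulse CP-mode drive producing
    ``reference_b1rms`` uT of mean B1rms over the mask (with the stated
    ``duty`` factor) yields a worst-VOP SAR of ``target_sar`` W/kg.  The
    default target of half the 20 W/kg limit leaves the optimizer
    headroom before the CP drive caps.  Deterministic per seed.
    """
    if n_vop < 1:
        raise ValueError("need at least one VOP")
    nch = setup.n_channels
    rng = np.random.default_rng(seed)
    mats = np.empty((n_vop, nch, nch), dtype=complex)
    for v in range(n_vop):
        g = rng.standard_normal((nch, 1)) + 1j * rng.standard_normal((nch, 1))
        q = (0.3 / nch) * (g @ g.conj().T)
        q += np.diag(1.0 + rng.uniform(0.0, 0.3, nch)) / nch
        mats[v] = 0.5 * (q + q.conj().T)

    # reference CP drive: scalar w_cp such that mean mask B1rms == target
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(nch) / nch)
    cp_field = np.abs(
        np.tensordot(phases, setup.sensitivities, axes=(0, 0))
    )[setup.mask]
    w_cp = reference_b1rms / (float(cp_field.mean()) * np.sqrt(duty))
    w_ref = WeightSet((w_cp * phases)[None, :])
    raw = sar_per_vop(WeightSet(w_ref.w), VOPSet(mats, sar_limit=sar_limit), duty)
    mats *= target_sar / raw.max()
    return VOPSet(
        matrices=mats,
        sar_limit=sar_limit,
        meta={
            "generator": "synthetic",
            "seed": int(seed),
            "target_sar_w_per_kg": target_sar,
            "reference_b1rms_ut": reference_b1rms,
            "reference_duty": duty,
            "reference_cp_voltage": float(w_cp),
            "duty_convention": "per_V2_times_TR_duty",
        },
    )


def save_vops(vops: VOPSet, path) -> None:
    """Write a VOP set to HDF5 (complex matrices + calibration metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("matrices", data=vops.matrices)
        f.attrs["sar_limit"] = vops.sar_limit
        f.attrs["n_channels"] = vops.n_channels
        for k, v in vops.meta.items():
            f.attrs[f"meta_{k}"] = v


def load_vops(path) -> VOPSet:
    """Load a VOP set written by :func:`save_vops`."""
    import h5py

    with h5py.File(path, "r") as f:
        mats = f["matrices"][...]
        sar_limit = float(f.attrs["sar_limit"])
        meta = {
            k[len("meta_") :]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
    return VOPSet(matrices=mats, sar_limit=sar_limit, meta=meta)
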