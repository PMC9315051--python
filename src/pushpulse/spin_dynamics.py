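"""Binary spin-bath dynamics: hard-pulse rotations, SPGR steady state, MTR.

Free-water magnetization obeys the Bloch equation; over a short RF pulse
relaxation is negligible and the dynamics reduce to a product of per-step
rotations about the instantaneous effective field.  The semisolid pool has
no transverse magnetization (T2s ~ 10 us): its longitudinal component
simply saturates at the average rate <W>, so the two-pool response to a
pulse factorizes into a free-water rotation and a semisolid decay
exp(-<W> tau).  This decoupling is what makes the free-water "flip angle"
of a saturation pulse irrelevant to MT contrast — gradient blips between
sub-pulses scramble the flip angle but cannot touch <W>.

The steady state of an MT-weighted spoiled gradient-echo (SPGR) sequence
is computed from the per-TR affine map on (Mzf, Mzs): instantaneous
excitation scales Mzf by cos(alpha) (ideal spoiling), then the coupled
relaxation/exchange/saturation generator acts continuously over the TR
(continuous-wave approximation, appropriate for short-TR sequences; a
discrete per-pulse saturation event is available behind
``saturation_mode='discrete'`` for sensitivity checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import GAMMA_RAD_PER_S_PER_UT
from .coil_fields import TransmitSetup
from .saturation_physics import (
    Lineshape,
    SaturationPulseSpec,
    WeightSet,
    compute_b1rms,
    lineshape_value,
)


class NoSteadyStateError(RuntimeError):
    """The per-TR propagator is not a contraction (unphysical parameters)."""


@dataclass
class TissueParams:
    """Two-pool tissue parameters.

    ``f`` is the semisolid pool fraction M0s/(M0s + M0f); the fundamental
    exchange rate ``k`` fixes kfs = k*f and ksf = k*(1-f), which satisfies
    detailed balance with M0f = 1-f and M0s = f (total magnetization 1).
    """

    r1f: float = 0.4
    t2f: float = 0.06
    f: float = 0.1357
    k: float = 32.79
    r1s: float = 1.85
    lineshape: Lineshape = field(default_factory=Lineshape)

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError("pool fraction f must be in [0, 1)")
        if min(self.r1f, self.t2f, self.k, self.r1s) < 0:
            raise ValueError("rates must be non-negative")

    @property
    def kfs(self) -> float:
        return self.k * self.f

    @property
    def ksf(self) -> float:
        return self.k * (1.0 - self.f)

    @property
    def m0f(self) -> float:
        return 1.0 - self.f

    @property
    def m0s(self) -> float:
        return self.f


def white_matter() -> TissueParams:
    """White-matter two-pool parameter set (shipped JSON asset)."""
    path = resources.files("pushpulse.data").joinpath("tissue_params.json")
    data = json.loads(path.read_text())["white_matter"]
    ls = data["lineshape"]
    return TissueParams(
        r1f=data["R1f_per_s"],
        t2f=data["T2f_s"],
        f=data["f"],
        k=data["k_per_s"],
        r1s=data["R1s_per_s"],
        lineshape=Lineshape(
            kind=ls["kind"], t2s=ls["T2s_s"], chemical_shift_hz=ls["shift_hz"]
        ),
    )


@dataclass
class SequenceSpec:
    """MT-weighted SPGR sequence: TR, excitation flip angle, saturation.

    The excitation is CP-mode and treated as spatially uniform with ideal
    spoiling; ``saturation_mode`` selects continuous-wave ('cw', default)
    or discrete per-TR-event ('discrete') application of <W>.
    """

    tr: float = 22e-3
    alpha_exc_deg: float = 5.0
    saturation: SaturationPulseSpec | None = None
    saturation_mode: str = "cw"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if not (0.0 <= self.alpha_exc_deg <= 90.0):
            raise ValueError("excitation flip angle must be in [0, 90] degrees")
        if self.saturation_mode not in ("cw", "discrete"):
            raise ValueError("saturation_mode must be 'cw' or 'discrete'")
        if self.saturation is not None and self.saturation.tr != self.tr:
            raise ValueError("saturation pulse TR must match the sequence TR")


@dataclass
class MTRResult:
    """Reference and saturated steady-state signal maps plus MTR (%)."""

    m_ref: np.ndarray
    m_sat: np.ndarray
    mtr: np.ndarray
    mask: np.ndarray
    b1rms: np.ndarray


# ---------------------------------------------------------------------------
# Hard-pulse rotations
# ---------------------------------------------------------------------------


def _rodrigues_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis by an angle (right-hand rule)."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
            [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
            [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
        ]
    )


def hard_pulse_propagate(
    b1_series_ut: np.ndarray, dbz_hz: float, dt: float
) -> np.ndarray:
    """Net rotation of the free-water magnetization over a sampled pulse.

    Each sample of the complex B1 series (uT) acts for ``dt`` seconds as a
    rotation about the effective field (gamma*B1x, gamma*B1y, 2*pi*dbz);
    the result is the left-multiplied product of the per-step rotations —
    a proper rotation matrix (orthogonal, det 1).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b1 = np.asarray(b1_series_ut, dtype=complex)
    wz = 2.0 * np.pi * dbz_hz
    r = np.eye(3)
    for b in b1:
        u = np.array([GAMMA_RAD_PER_S_PER_UT * b.real, GAMMA_RAD_PER_S_PER_UT * b.imag, wz])
        norm = np.linalg.norm(u)
        if norm == 0.0:
            continue
        r = _rodrigues_matrix(u / norm, -norm * dt) @ r
    return r


def _rotate_vectors(m: np.ndarray, axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of (N, 3) vectors about per-row axes/angles."""
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    safe = np.where(norms == 0.0, 1.0, norms)
    n = axes / safe
    phi = (angles * norms[:, 0])[:, None]
    c, s = np.cos(phi), np.sin(phi)
    ndm = np.sum(n * m, axis=1, keepdims=True)
    out = m * c + np.cross(n, m) * s + n * ndm * (1.0 - c)
    return np.where(norms == 0.0, m, out)


def flip_angle_map(
    setup: TransmitSetup,
    spec: SaturationPulseSpec,
    weights: WeightSet,
    eval_offset_hz: float | None = None,
) -> np.ndarray:
    """Flip angle (degrees) of the saturation train for spins resonant at
    ``eval_offset_hz`` from water (default: the RF offset frequency).

    Everything is computed in the frame rotating at the RF carrier: a
    spin whose local resonance is ``eval_offset_hz + dB0(r)`` precesses at
    ``eval_offset_hz + dB0(r) - offset`` there, so for the default choice
    the sub-pulses act on-resonance (their full rotation) and only dB0
    and the gradient-blip phase rolls rotate the magnetization between
    sub-pulses.  The flip angle is the polar angle of the net rotation
    applied to equilibrium (+z).

    This map exists to quantify exactly what the B1rms forward model
    ignores: blips reshape this map while leaving B1rms untouched.
    """
    if weights.w.shape != (spec.n_subpulses, setup.n_channels):
        raise ValueError("weights shape does not match (Nsp, Nch)")
    if eval_offset_hz is None:
        eval_offset_hz = spec.offset_hz
    mask = setup.mask
    s = setup.sensitivities[:, mask]  # (Nch, Nvox)
    fields = weights.w @ s  # (Nsp, Nvox) complex, uT per unit envelope
    db0 = setup.db0_hz[mask]
    # detuning from the RF carrier, rad/s per voxel
    wz = 2.0 * np.pi * (eval_offset_hz + db0 - spec.offset_hz)

    # blip phase at each voxel: antisymmetric roll about the FOV center
    coords = setup.coordinates_mm()
    grids = np.meshgrid(*coords, indexing="ij")
    blip_phases = []
    for blip in spec.inter_pulse_blips or []:
        phase = np.zeros(mask.shape)
        for ax, cycles in enumerate(blip.phase_rolls):
            if cycles != 0.0:
                phase += 2.0 * np.pi * cycles * grids[ax] / setup.fov_mm[ax]
        blip_phases.append((phase[mask], blip.duration_s))

    nvox = fields.shape[1]
    m = np.tile(np.array([0.0, 0.0, 1.0]), (nvox, 1))
    dt = spec.waveform.dt
    env = spec.waveform.samples
    gamma = GAMMA_RAD_PER_S_PER_UT
    axes = np.empty((nvox, 3))
    for p in range(spec.n_subpulses):
        for b in env:
            b1 = fields[p] * b  # (Nvox,) complex uT
            axes[:, 0] = gamma * b1.real
            axes[:, 1] = gamma * b1.imag
            axes[:, 2] = wz
            m = _rotate_vectors(m, axes, -dt)
        if p < spec.n_subpulses - 1 and blip_phases:
            phase, dur = blip_phases[p]
            angle = -(wz * dur + phase)
            c, sn = np.cos(angle), np.sin(angle)
            mx = m[:, 0] * c - m[:, 1] * sn
            my = m[:, 0] * sn + m[:, 1] * c
            m[:, 0], m[:, 1] = mx, my
    flip = np.degrees(np.arccos(np.clip(m[:, 2], -1.0, 1.0)))
    out = np.zeros(mask.shape)
    out[mask] = flip
    return out


def semisolid_decay(w_rate: float | np.ndarray, tau: float) -> float | np.ndarray:
    """Longitudinal semisolid survival factor exp(-<W> tau)."""
    w_rate = np.asarray(w_rate, dtype=float)
    if np.any(w_rate < 0) or tau < 0:
        raise ValueError("W and tau must be non-negative")
    out = np.exp(-w_rate * tau)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# SPGR steady state of the two-pool system
# ---------------------------------------------------------------------------


def _expm2(a, b, c, d):
    """Vectorized expm of 2x2 matrices [[a, b], [c, d]] (broadcast arrays)."""
    a, b, c, d = np.broadcast_arrays(*(np.asarray(x, float) for x in (a, b, c, d)))
    mu = 0.5 * (a + d)
    s2 = 0.25 * (a - d) ** 2 + b * c
    s = np.sqrt(np.abs(s2))
    # cosh/sinc for s2 >= 0, cos/sinc for s2 < 0; series-safe near zero
    pos = s2 >= 0
    f = np.where(pos, np.cosh(s), np.cos(s))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(
            s > 1e-8,
            np.where(pos, np.sinh(s), np.sin(s)) / np.where(s == 0, 1.0, s),
            1.0 + np.where(pos, 1.0, -1.0) * s2 / 6.0,
        )
    emu = np.exp(mu)
    e11 = emu * (f + g * (a - mu))
    e12 = emu * g * b
    e21 = emu * g * c
    e22 = emu * (f + g * (d - mu))
    return e11, e12, e21, e22


def _solve2(a11, a12, a21, a22, r1, r2):
    det = a11 * a22 - a12 * a21
    return (a22 * r1 - a12 * r2) / det, (a11 * r2 - a21 * r1) / det


def spgr_mt_steady_state(
    tissue: TissueParams,
    seq: SequenceSpec,
    w_map: np.ndarray | float,
    alpha_deg: np.ndarray | float | None = None,
) -> np.ndarray:
    """Steady-state SPGR signal (fraction of M0) under MT saturation.

    Per voxel the TR map on x = (Mzf, Mzs) is x -> E C x + d, where C
    scales Mzf by cos(alpha) (instantaneous excitation, ideal spoiling)
    and E = expm(Lambda TR) with

        Lambda = [[-R1f - kfs,        ksf     ],
                  [    kfs,    -R1s - ksf - W ]]

    (continuous-wave saturation at rate W over the whole TR) and
    d = Lambda^{-1} (E - I) c with c = (R1f M0f, R1s M0s).  The steady
    state is the fixed point x* = (I - E C)^{-1} d and the returned signal
    is sin(alpha) * Mzf* (readout immediately after excitation; TE decay
    is common to Msat and Mref and cancels in MTR).

    With ``saturation_mode='discrete'`` the saturation instead acts as a
    per-TR event exp(-W TR) on Mzs, with W-free evolution in between.

    Raises :class:`NoSteadyStateError` if the TR map is not a contraction.
    """
    w_map = np.asarray(w_map, dtype=float)
    if np.any(w_map < 0):
        raise ValueError("W must be non-negative")
    if alpha_deg is None:
        alpha_deg = seq.alpha_exc_deg
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    if np.any(alpha < 0) or np.any(alpha > np.pi / 2):
        raise ValueError("flip angle must be in [0, 90] degrees")
    w_map, alpha = np.broadcast_arrays(w_map, alpha)

    tr = seq.tr
    kfs, ksf = tissue.kfs, tissue.ksf
    a = -tissue.r1f - kfs
    b = ksf
    c2 = kfs
    cvec = (tissue.r1f * tissue.m0f, tissue.r1s * tissue.m0s)

    if seq.saturation_mode == "cw":
        d22 = -tissue.r1s - ksf - w_map
        e11, e12, e21, e22 = _expm2(a * tr, b * tr, c2 * tr, d22 * tr)
        # d = Lambda^{-1} (E - I) c
        r1 = (e11 - 1.0) * cvec[0] + e12 * cvec[1]
        r2 = e21 * cvec[0] + (e22 - 1.0) * cvec[1]
        d1, d2 = _solve2(a, b, c2, d22, r1, r2)
        sat1 = np.ones_like(w_map)
    else:
        d22 = np.full_like(w_map, -tissue.r1s - ksf)
        e11, e12, e21, e22 = _expm2(a * tr, b * tr, c2 * tr, d22 * tr)
        r1 = (e11 - 1.0) * cvec[0] + e12 * cvec[1]
        r2 = e21 * cvec[0] + (e22 - 1.0) * cvec[1]
        d1, d2 = _solve2(a, b, c2, d22, r1, r2)
        sat1 = np.exp(-w_map * tr)

    # per-TR linear part M = E * diag(cos(alpha), sat1_on_Mzs)
    ca = np.cos(alpha)
    m11 = e11 * ca
    m21 = e21 * ca
    m12 = e12 * sat1
    m22 = e22 * sat1

    # contraction check via eigenvalue magnitudes of the 2x2 map
    trm = m11 + m22
    detm = m11 * m22 - m12 * m21
    disc = np.asarray(trm**2 - 4.0 * detm, dtype=complex)
    lam = (np.abs(trm + np.sqrt(disc)) + 0.0) / 2.0
    if np.any(np.maximum(lam, np.abs(detm) / np.maximum(lam, 1e-300)) >= 1.0):
        raise NoSteadyStateError("per-TR propagator has spectral radius >= 1")

    x1, _ = _solve2(1.0 - m11, -m12, -m21, 1.0 - m22, d1, d2)
    signal = np.sin(alpha) * x1
    return signal if signal.ndim else float(signal)


def iterate_spgr_mt(
    tissue: TissueParams,
    seq: SequenceSpec,
    w_rate: float,
    alpha_deg: float,
    n_tr: int,
) -> float:
    """Long-run iteration of the per-TR map from thermal equilibrium.

    Brute-force counterpart of :func:`spgr_mt_steady_state`, used to
    verify the fixed-point solution.
    """
    from scipy.linalg import expm

    alpha = np.deg2rad(alpha_deg)
    lam = np.array(
        [
            [-tissue.r1f - tissue.kfs, tissue.ksf],
            [tissue.kfs, -tissue.r1s - tissue.ksf - w_rate],
        ]
    )
    cvec = np.array([tissue.r1f * tissue.m0f, tissue.r1s * tissue.m0s])
    e = expm(lam * seq.tr)
    d = np.linalg.solve(lam, (e - np.eye(2)) @ cvec)
    x = np.array([tissue.m0f, tissue.m0s])
    cdiag = np.array([np.cos(alpha), 1.0])
    for _ in range(n_tr):
        x = e @ (cdiag * x) + d
    return float(np.sin(alpha) * x[0])


def simulate_mtr(
    setup: TransmitSetup,
    tissue: TissueParams,
    seq: SequenceSpec,
    sat_weights: WeightSet,
) -> MTRResult:
    """Steady-state MTR map for a saturation weight set.

    Msat uses W(r) derived from the voxel's sequence-level B1rms through
    the tissue lineshape at the RF offset; Mref is the identical sequence
    with the saturation weights zeroed.  Tissue is uniform across the
    mask, so the MTR map directly visualizes the spatial saturation
    pattern.  MTR(%) = 100 (Mref - Msat)/Mref.
    """
    if seq.saturation is None:
        raise ValueError("sequence has no saturation pulse spec")
    spec = seq.saturation
    b1rms = compute_b1rms(setup, spec, sat_weights)
    g = lineshape_value(tissue.lineshape, spec.offset_hz)
    mask = setup.mask
    w_vox = np.pi * GAMMA_RAD_PER_S_PER_UT**2 * g * b1rms[mask] ** 2
    m_sat_vox = spgr_mt_steady_state(tissue, seq, w_vox)
    m_ref_scalar = spgr_mt_steady_state(tissue, seq, 0.0)
    m_ref = np.zeros(mask.shape)
    m_sat = np.zeros(mask.shape)
    mtr = np.zeros(mask.shape)
    m_ref[mask] = m_ref_scalar
    m_sat[mask] = m_sat_vox
    mtr[mask] = 100.0 * (m_ref_scalar - m_sat_vox) / m_ref_scalar
    return MTRResult(m_ref=m_ref, m_sat=m_sat, mtr=mtr, mask=mask, b1rms=b1rms)
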