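"""Sub-pulse waveforms, sequence-level mean-squared B1+, lineshapes and <W>.

The quantity the design optimizes is the sequence-level root-mean-squared
B1+ ("B1rms"): for a train of Nsp identically shaped sub-pulses with
per-channel complex weights w_jp (volts) applied on transmit sensitivities
s_j(r) (uT/V),

    B1rms(r)^2 = sum_p | sum_j s_j(r) w_jp |^2 * bbar2

where ``bbar2`` is the mean square of the shared normalized envelope b(t)
averaged over the sequence TR.  Semisolid protons saturate at the average
rate

    <W> = pi * gamma^2 * g(Delta) * B1rms^2

with g the absorption lineshape (seconds; unit area over angular
frequency) evaluated at the irradiation offset relative to the line
center.  Because B1rms^2 is a sum of per-sub-pulse intensities, gradient
blips played between sub-pulses never change it — only the free-water
"flip angle" (see :mod:`pushpulse.spin_dynamics`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy import integrate

from .coil_fields import GradientBlip, TransmitSetup
from .constants import GAMMA_RAD_PER_S_PER_UT


@dataclass
class SubPulseWaveform:
    """Dimensionless complex RF envelope with peak magnitude 1.

    Samples live on the midpoint grid t_k = (k + 1/2) dt, so the duration
    is exactly ``n_samples * dt`` and symmetric envelopes are sampled
    symmetrically about tau/2.
    """

    samples: np.ndarray
    dt: float
    shape_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        peak = np.max(np.abs(self.samples))
        if not np.isclose(peak, 1.0, rtol=1e-9, atol=0):
            raise ValueError("waveform must be peak-normalized to 1")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) + 0.5) * self.dt

    def energy_integral(self) -> float:
        """integral of |b(t)|^2 dt over the pulse, midpoint rule (s)."""
        return float(np.sum(np.abs(self.samples) ** 2) * self.dt)


def make_gaussian_subpulse(tbp: float, tau: float, dt: float) -> SubPulseWaveform:
    """Truncated Gaussian envelope with the given time-bandwidth product.

    ``tbp`` is duration times spectral FWHM, so the FWHM bandwidth is
    tbp/tau; the time-domain standard deviation follows from the Fourier
    pair sigma_f = 1/(2 pi sigma_t).  The envelope is truncated at
    [0, tau], symmetric about tau/2, and renormalized so the largest
    sample is exactly 1.
    """
    if tbp <= 0:
        raise ValueError("tbp must be positive")
    if dt >= tau:
        raise ValueError("dt must be smaller than tau")
    if tau < 10 * dt:
        raise ValueError("need at least 10 samples across the pulse")
    bw_fwhm = tbp / tau
    sigma_f = bw_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    n = int(round(tau / dt))
    t = (np.arange(n) + 0.5) * dt
    env = np.exp(-((t - tau / 2.0) ** 2) / (2.0 * sigma_t**2))
    env = env / env.max()
    return SubPulseWaveform(
        samples=env,
        dt=dt,
        shape_meta={
            "kind": "gaussian",
            "time_bandwidth_product": tbp,
            "sigma_t": sigma_t,
            "tau": tau,
        },
    )


def make_rect_subpulse(tau: float, dt: float) -> SubPulseWaveform:
    """Constant unit envelope of duration tau."""
    if dt >= tau:
        raise ValueError("dt must be smaller than tau")
    n = int(round(tau / dt))
    return SubPulseWaveform(samples=np.ones(n), dt=dt, shape_meta={"kind": "rect"})


@dataclass
class SaturationPulseSpec:
    """A saturation pulse train: Nsp copies of one envelope at offset omega.

    ``inter_pulse_blips`` holds the gradient blips played between
    consecutive sub-pulses (length Nsp - 1; may be empty for Nsp = 1).
    """

    waveform: SubPulseWaveform
    n_subpulses: int = 1
    offset_hz: float = 2000.0
    tr: float = 22e-3
    inter_pulse_blips: list[GradientBlip] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_subpulses < 1:
            raise ValueError("need at least one sub-pulse")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.inter_pulse_blips and len(self.inter_pulse_blips) != self.n_subpulses - 1:
            raise ValueError("need Nsp - 1 inter-pulse blips (or none)")
        total = self.n_subpulses * self.waveform.duration + sum(
            b.duration_s for b in self.inter_pulse_blips
        )
        if self.tr < total:
            raise ValueError("TR shorter than the saturation pulse train")
        bw = self.waveform.shape_meta.get("time_bandwidth_product")
        if bw is not None:
            bandwidth = bw / self.waveform.duration
            if abs(self.offset_hz) < 2.0 * bandwidth:
                warnings.warn(
                    "offset frequency is within 2x the sub-pulse bandwidth; "
                    "the zero-flip-angle assumption for free water may fail",
                    stacklevel=2,
                )


@dataclass
class WeightSet:
    """Complex sub-pulse/channel amplitudes w_jp in volts, shape (Nsp, Nch)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=complex))
        if self.w.ndim != 2:
            raise ValueError("weights must be a 2D (Nsp, Nch) array")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")

    @property
    def n_subpulses(self) -> int:
        return self.w.shape[0]

    @property
    def n_channels(self) -> int:
        return self.w.shape[1]


def normalized_mean_square(waveform: SubPulseWaveform, tr: float) -> float:
    """TR-averaged mean square of the normalized envelope (dimensionless).

    Returns (1/TR) * integral |b(t)|^2 dt over one sub-pulse; RF-free gaps
    contribute nothing.
    """
    if tr < waveform.duration:
        raise ValueError("TR must be at least the sub-pulse duration")
    return waveform.energy_integral() / tr


def compute_b1rms(
    setup: TransmitSetup, spec: SaturationPulseSpec, weights: WeightSet
) -> np.ndarray:
    """Per-voxel sequence-level B1rms map in uT (zero outside the mask).

    B1rms(r) = sqrt( sum_p |sum_j s_j(r) w_jp|^2 * bbar2 ); the total is a
    sum of per-sub-pulse intensities, so it is independent of any
    inter-pulse gradient blips by construction.
    """
    if weights.w.shape != (spec.n_subpulses, setup.n_channels):
        raise ValueError(
            f"weights shape {weights.w.shape} does not match "
            f"(Nsp={spec.n_subpulses}, Nch={setup.n_channels})"
        )
    bbar2 = normalized_mean_square(spec.waveform, spec.tr)
    s = setup.sensitivities[:, setup.mask]  # (Nch, Nvox)
    fields = weights.w @ s  # (Nsp, Nvox)
    ms = np.sum(np.abs(fields) ** 2, axis=0) * bbar2
    out = np.zeros(setup.grid_shape)
    out[setup.mask] = np.sqrt(ms)
    return out


# ---------------------------------------------------------------------------
# Absorption lineshapes
# ---------------------------------------------------------------------------

#: below this offset from the line center the super-Lorentzian integrand is
#: nearly singular at the magic angle; values are cubic-extrapolated from
#: the [1, 2] kHz band instead (the standard qMT convention).
SUPER_LORENTZIAN_CUTOFF_HZ = 1000.0


@dataclass
class Lineshape:
    """Semisolid absorption lineshape g (units: seconds).

    ``chemical_shift_hz`` is the center of the line relative to water
    (white matter: about -2.6 ppm, i.e. -773 Hz at 297.2 MHz); callers
    pass offsets measured from water and the shift is applied internally.
    Normalization follows the qMT convention of unit area over angular
    frequency, so <W> = pi * gamma^2 * g * B1^2 is in s^-1.
    """

    kind: str = "super_lorentzian"
    t2s: float = 9.6e-6
    chemical_shift_hz: float = -773.0

    def __post_init__(self) -> None:
        if self.kind not in ("super_lorentzian", "gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape kind {self.kind!r}")
        if self.t2s <= 0:
            raise ValueError("T2s must be positive")


def _super_lorentzian_integral(delta_hz: float, t2s: float) -> float:
    """Angular integral over fiber orientations, adaptive quadrature."""

    def integrand(theta: float) -> float:
        c = 3.0 * np.cos(theta) ** 2 - 1.0
        if c == 0.0:
            return 0.0
        arg = 2.0 * np.pi * delta_hz * t2s / c
        return np.sin(theta) * (t2s / abs(c)) * np.exp(-2.0 * arg**2)

    magic = np.arccos(1.0 / np.sqrt(3.0))
    val, _ = integrate.quad(
        integrand, 0.0, np.pi / 2.0, points=[magic], limit=200
    )
    return float(np.sqrt(2.0 / np.pi) * val)


def lineshape_value(
    ls: Lineshape, delta_hz: float, return_meta: bool = False
) -> float | tuple[float, dict]:
    """Evaluate g at an offset ``delta_hz`` measured from water (seconds).

    The offset is first shifted by the line center.  Super-Lorentzian
    values inside the near-resonance cutoff are cubic-extrapolated from
    the [1, 2] kHz band and flagged in the metadata.
    """
    d = float(delta_hz) - ls.chemical_shift_hz
    meta = {"extrapolated": False, "effective_offset_hz": d}
    x = 2.0 * np.pi * d * ls.t2s
    if ls.kind == "gaussian":
        g = (ls.t2s / np.sqrt(2.0 * np.pi)) * np.exp(-(x**2) / 2.0)
    elif ls.kind == "lorentzian":
        g = (ls.t2s / np.pi) / (1.0 + x**2)
    else:
        ad = abs(d)
        if ad >= SUPER_LORENTZIAN_CUTOFF_HZ:
            g = _super_lorentzian_integral(ad, ls.t2s)
        else:
            nodes = np.linspace(1000.0, 2000.0, 4)
            vals = [_super_lorentzian_integral(f, ls.t2s) for f in nodes]
            g = float(np.polyval(np.polyfit(nodes, vals, 3), ad))
            meta["extrapolated"] = True
    g = float(g)
    if return_meta:
        return g, meta
    return g


def mean_saturation_rate(
    b1rms: float | np.ndarray, ls: Lineshape, delta_hz: float
) -> float | np.ndarray:
    """Average semisolid saturation rate <W> in s^-1.

    <W> = pi * gamma^2 * g(delta) * b1rms^2 with gamma in rad/s/uT and g
    in seconds.  Whether ``b1rms`` was averaged over the pulse duration or
    the TR is the caller's choice; the formula is agnostic.
    """
    b1rms = np.asarray(b1rms, dtype=float)
    if np.any(b1rms < 0):
        raise ValueError("b1rms must be non-negative")
    g = lineshape_value(ls, delta_hz)
    w = np.pi * GAMMA_RAD_PER_S_PER_UT**2 * g * b1rms**2
    return float(w) if w.ndim == 0 else w
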