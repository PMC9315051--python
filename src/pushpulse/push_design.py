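"""Constrained magnitude-least-squares design of saturation sub-pulse weights.

The design variable is the complex weight matrix w_jp (sub-pulse p,
channel j, volts).  The objective is a magnitude least-squares fit of the
achieved sequence-level B1rms to a target beta over a region of interest,

    min_w  sum_r ( sqrt( sum_p |sum_j s_j(r) w_jp|^2 * bbar2 + eps ) - beta(r) )^2

subject to local SAR at every virtual observation point, TR-averaged
power per channel, and peak voltage per sub-pulse and channel.  With one
sub-pulse this reduces to classical magnitude least-squares B1+ shimming;
extra sub-pulses enlarge the feasible set (any Nsp solution embeds into
Nsp+1 with a zero-padded sub-pulse), so the best cost is non-increasing
in Nsp.  A CP-mode baseline (fixed circularly-polarized phases, one real
amplitude) and an independent variable-exchange MLS solver are provided
as references.

Weights are parameterized as stacked real/imaginary parts with analytic
gradients for both the objective and every constraint; the solves use
sequential quadratic programming (scipy SLSQP) with a multi-start
strategy.  All randomness is owned by the (seed, n_starts) arguments, so
reruns are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .coil_fields import TransmitSetup
from .rf_constraints import (
    ConstraintReport,
    HardwareLimits,
    VOPSet,
    check_feasible,
    max_feasible_scale,
)
from .saturation_physics import (
    SaturationPulseSpec,
    WeightSet,
    normalized_mean_square,
)

#: smoothing inside the square root so the MLS objective stays
#: differentiable where the combined field has a null (uT^2)
MLS_EPSILON_UT2 = 1e-12


class InfeasibleDesignError(RuntimeError):
    """No feasible point found across all starts (carries the best report)."""

    def __init__(self, message: str, report: ConstraintReport | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class DesignProblem:
    """A saturation-homogeneity design instance.

    ``beta_ut`` is the target B1rms in uT, either a scalar (spatially
    uniform, the shipped experiments) or a per-voxel map over the grid.
    ``region`` restricts the least-squares residual (e.g. one axial
    slice); hardware constraints are always global regardless of region.
    """

    setup: TransmitSetup
    spec: SaturationPulseSpec
    beta_ut: float | np.ndarray
    vops: VOPSet
    limits: HardwareLimits
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.region is None:
            self.region = self.setup.mask
        self.region = np.asarray(self.region, dtype=bool)
        if self.region.shape != self.setup.mask.shape:
            raise ValueError("region must live on the setup grid")
        if np.any(self.region & ~self.setup.mask):
            raise ValueError("region must be a subset of the mask")
        if not self.region.any():
            raise ValueError("region is empty")
        if np.isscalar(self.beta_ut):
            if self.beta_ut <= 0:
                raise ValueError("beta must be positive")
        else:
            self.beta_ut = np.asarray(self.beta_ut, dtype=float)
            if np.any(self.beta_ut[self.region] <= 0):
                raise ValueError("beta must be positive inside the region")

    def beta_vector(self) -> np.ndarray:
        if np.isscalar(self.beta_ut):
            return np.full(int(self.region.sum()), float(self.beta_ut))
        return self.beta_ut[self.region]


@dataclass
class DesignResult:
    """Optimized weights plus diagnostics; always audited feasible."""

    weights: WeightSet
    cost: float
    nrmse: float
    b1rms: np.ndarray
    constraint_report: ConstraintReport
    n_starts: int
    best_start: int
    converged: bool
    iterations: int
    per_start_costs: list = field(default_factory=list)
    method: str = "push"


def canonicalize_weights(w: np.ndarray) -> np.ndarray:
    """Rotate each sub-pulse's global phase so its first channel is real >= 0.

    B1rms, SAR and power are invariant to a global phase per sub-pulse;
    canonicalizing makes reported solutions comparable across runs.  If
    the first channel is (numerically) zero the largest-magnitude channel
    anchors the phase instead.
    """
    w = np.array(w, dtype=complex)
    for p in range(w.shape[0]):
        ref = w[p, 0]
        if abs(ref) < 1e-12 * max(np.abs(w[p]).max(), 1.0):
            ref = w[p, np.argmax(np.abs(w[p]))]
        if abs(ref) > 0:
            w[p] *= np.exp(-1j * np.angle(ref))
    return w


def _pack(w: np.ndarray) -> np.ndarray:
    return np.concatenate([w.real.ravel(), w.imag.ravel()])


def _unpack(x: np.ndarray, nsp: int, nch: int) -> np.ndarray:
    half = nsp * nch
    return (x[:half] + 1j * x[half:]).reshape(nsp, nch)


class _PushObjective:
    """MLS objective with analytic gradient over packed real variables."""

    def __init__(self, s_region: np.ndarray, beta: np.ndarray, bbar2: float, nsp: int):
        self.s = s_region  # (Nvox, Nch) complex
        self.beta = beta
        self.bbar2 = bbar2
        self.nsp = nsp
        self.nch = s_region.shape[1]

    def b1rms(self, w: np.ndarray) -> np.ndarray:
        f = self.s @ w.T  # (Nvox, Nsp)
        return np.sqrt(self.bbar2 * np.sum(np.abs(f) ** 2, axis=1) + MLS_EPSILON_UT2)

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        w = _unpack(x, self.nsp, self.nch)
        f = self.s @ w.T  # (Nvox, Nsp)
        rms = np.sqrt(self.bbar2 * np.sum(np.abs(f) ** 2, axis=1) + MLS_EPSILON_UT2)
        rho = rms - self.beta
        cost = float(np.dot(rho, rho))
        # d rms / d Re(w_jp) = bbar2 Re(conj(F_p) s_j)/rms ; Im analogous
        coef = (2.0 * rho * self.bbar2 / rms)[:, None]  # (Nvox, 1)
        grad_re = np.empty((self.nsp, self.nch))
        grad_im = np.empty((self.nsp, self.nch))
        for p in range(self.nsp):
            g = np.conj(f[:, p])[:, None] * self.s  # (Nvox, Nch)
            grad_re[p] = np.sum(coef * g.real, axis=0)
            grad_im[p] = np.sum(coef * (-g.imag), axis=0)
        return cost, np.concatenate([grad_re.ravel(), grad_im.ravel()])


def _build_constraints(
    problem: DesignProblem, nsp: int, duty: float
) -> list[dict]:
    """Inequality constraints g(x) >= 0 with analytic Jacobians."""
    nch = problem.setup.n_channels
    vops, limits = problem.vops, problem.limits
    qmats = vops.matrices

    def sar_fun(x):
        w = _unpack(x, nsp, nch)
        qw = np.einsum("vjk,pk->vpj", qmats, w)
        sar = duty * np.real(np.einsum("pj,vpj->v", np.conj(w), qw))
        return vops.sar_limit - sar

    def sar_jac(x):
        w = _unpack(x, nsp, nch)
        qw = np.einsum("vjk,pk->vpj", qmats, w)  # (V, Nsp, Nch)
        jre = -2.0 * duty * qw.real.reshape(qmats.shape[0], -1)
        jim = -2.0 * duty * qw.imag.reshape(qmats.shape[0], -1)
        return np.concatenate([jre, jim], axis=1)

    pcoef = duty / limits.impedance

    def pow_fun(x):
        w = _unpack(x, nsp, nch)
        return limits.p_max - pcoef * np.sum(np.abs(w) ** 2, axis=0)

    def pow_jac(x):
        w = _unpack(x, nsp, nch)
        jac = np.zeros((nch, 2 * nsp * nch))
        for j in range(nch):
            idx = j + nch * np.arange(nsp)
            jac[j, idx] = -2.0 * pcoef * w.real[:, j]
            jac[j, idx + nsp * nch] = -2.0 * pcoef * w.imag[:, j]
        return jac

    vmax2 = limits.v_max**2

    def volt_fun(x):
        w = _unpack(x, nsp, nch)
        return vmax2 - (np.abs(w) ** 2).ravel()

    def volt_jac(x):
        n = nsp * nch
        jac = np.zeros((n, 2 * n))
        jac[np.arange(n), np.arange(n)] = -2.0 * x[:n]
        jac[np.arange(n), np.arange(n) + n] = -2.0 * x[n : 2 * n]
        return jac

    return [
        {"type": "ineq", "fun": sar_fun, "jac": sar_jac},
        {"type": "ineq", "fun": pow_fun, "jac": pow_jac},
        {"type": "ineq", "fun": volt_fun, "jac": volt_jac},
    ]


def _audit_and_repair(
    w: np.ndarray, problem: DesignProblem, spec: SaturationPulseSpec
) -> tuple[np.ndarray, ConstraintReport]:
    """Scale a solution down (quadratic constraints shrink with scale) if it
    overshoots the limits by more than the solver tolerance."""
    ws = WeightSet(w)
    rep = check_feasible(
        ws, problem.vops, problem.limits, spec.waveform, spec.tr
    )
    if not rep.feasible and np.abs(w).max() > 0:
        scale = max_feasible_scale(
            ws, problem.vops, problem.limits, spec.waveform, spec.tr
        )
        w = w * min(scale, 1.0)
        rep = check_feasible(
            WeightSet(w), problem.vops, problem.limits, spec.waveform, spec.tr
        )
    return w, rep


def _result_from_weights(
    problem: DesignProblem,
    spec: SaturationPulseSpec,
    w: np.ndarray,
    obj: _PushObjective,
    **kwargs,
) -> DesignResult:
    from .saturation_physics import compute_b1rms

    w = canonicalize_weights(w)
    ws = WeightSet(w)
    rep = check_feasible(ws, problem.vops, problem.limits, spec.waveform, spec.tr)
    rms = obj.b1rms(w)
    beta = obj.beta
    cost = float(np.sum((rms - beta) ** 2))
    nrmse = float(np.sqrt(cost / beta.size) / beta.mean())
    full = compute_b1rms(problem.setup, spec, ws)
    return DesignResult(
        weights=ws,
        cost=cost,
        nrmse=nrmse,
        b1rms=full,
        constraint_report=rep,
        **kwargs,
    )


def design_push(
    problem: DesignProblem,
    n_subpulses: int,
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 500,
    ftol: float = 1e-8,
) -> DesignResult:
    """Design PUSH-Nsp sub-pulse weights by constrained MLS optimization.

    Start 1 is the CP-mode solution split equally across sub-pulses;
    remaining starts draw uniform random phases with magnitudes at half
    the voltage bound, rescaled into the feasible set.  The best feasible
    local optimum over starts wins (ties below 1e-10 break toward the
    lowest start index).  Fully deterministic given (seed, n_starts).
    """
    if n_subpulses < 1:
        raise ValueError("need at least one sub-pulse")
    spec = SaturationPulseSpec(
        waveform=problem.spec.waveform,
        n_subpulses=n_subpulses,
        offset_hz=problem.spec.offset_hz,
        tr=problem.spec.tr,
    )
    setup = problem.setup
    nch = setup.n_channels
    bbar2 = normalized_mean_square(spec.waveform, spec.tr)
    s_region = setup.sensitivities[:, problem.region].T  # (Nvox, Nch)
    beta = problem.beta_vector()
    obj = _PushObjective(s_region, beta, bbar2, n_subpulses)
    constraints = _build_constraints(problem, n_subpulses, bbar2)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    cp = cp_mode_weights(problem, n_subpulses=n_subpulses)
    starts.append(cp.weights.w.copy())
    for _ in range(max(n_starts - 1, 0)):
        mag = 0.5 * problem.limits.v_max
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_subpulses, nch))
        w0 = mag * np.exp(1j * phase)
        scale = max_feasible_scale(
            WeightSet(w0), problem.vops, problem.limits, spec.waveform, spec.tr
        )
        starts.append(w0 * min(0.999 * scale, 1.0))

    best = None
    per_start = []
    for k, w0 in enumerate(starts[:n_starts]):
        res = optimize.minimize(
            obj,
            _pack(w0),
            jac=True,
            method="SLSQP",
            constraints=constraints,
            options={"maxiter": maxiter, "ftol": ftol},
        )
        w_opt, rep = _audit_and_repair(
            _unpack(res.x, n_subpulses, nch), problem, spec
        )
        cost = float(np.sum((obj.b1rms(w_opt) - beta) ** 2))
        per_start.append(cost)
        if not rep.feasible:
            continue
        entry = (cost, k, w_opt, res)
        if best is None or cost < best[0] - 1e-10:
            best = entry
    if best is None:
        raise InfeasibleDesignError(
            "no feasible solution across starts", report=rep
        )
    cost, k, w_opt, res = best
    return _result_from_weights(
        problem,
        spec,
        w_opt,
        obj,
        n_starts=len(starts[:n_starts]),
        best_start=k,
        converged=bool(res.success),
        iterations=int(res.nit),
        per_start_costs=per_start,
        method=f"push-{n_subpulses}",
    )


def cp_mode_weights(
    problem: DesignProblem, n_subpulses: int | None = None
) -> DesignResult:
    """CP-mode baseline: fixed circularly-polarized phases, one amplitude.

    Every sub-pulse carries w_j = w_cp exp(-i 2 pi (j-1)/Nch); the single
    real scalar w_cp >= 0 minimizes the same MLS objective subject to all
    constraints (1-D bounded minimization).  When a constraint binds,
    w_cp sits on the boundary and the delivered B1rms caps.
    """
    setup = problem.setup
    nch = setup.n_channels
    nsp = n_subpulses if n_subpulses is not None else problem.spec.n_subpulses
    spec = SaturationPulseSpec(
        waveform=problem.spec.waveform,
        n_subpulses=nsp,
        offset_hz=problem.spec.offset_hz,
        tr=problem.spec.tr,
    )
    bbar2 = normalized_mean_square(spec.waveform, spec.tr)
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(nch) / nch)
    unit = np.tile(phases, (nsp, 1))
    cap = max_feasible_scale(
        WeightSet(unit), problem.vops, problem.limits, spec.waveform, spec.tr
    )
    a = np.abs(problem.setup.sensitivities[:, problem.region].T @ phases)
    a_eff = a * np.sqrt(nsp * bbar2)  # achieved B1rms per volt of w_cp
    beta = problem.beta_vector()

    def cost_of(wcp: float) -> float:
        return float(np.sum((wcp * a_eff - beta) ** 2))

    res = optimize.minimize_scalar(cost_of, bounds=(0.0, cap), method="bounded",
                                   options={"xatol": 1e-12})
    wcp = float(res.x)
    # bounded Brent can stall a hair inside the boundary; snap if better
    for cand in (0.0, cap):
        if cost_of(cand) < cost_of(wcp):
            wcp = cand
    w = wcp * unit
    obj = _PushObjective(
        problem.setup.sensitivities[:, problem.region].T, beta, bbar2, nsp
    )
    return _result_from_weights(
        problem,
        spec,
        w,
        obj,
        n_starts=1,
        best_start=0,
        converged=True,
        iterations=int(getattr(res, "nfev", 0)),
        method="cp",
    )


def cp_closed_form_amplitude(problem: DesignProblem, n_subpulses: int = 1) -> float:
    """Unconstrained CP amplitude: scalar regression of achieved B1rms on beta.

    With w_cp >= 0 the magnitude fit is linear, so the optimum is
    sum(a beta)/sum(a^2) with a the per-voxel CP-mode B1rms per volt.
    Used as an oracle for :func:`cp_mode_weights` when constraints are
    inactive.
    """
    nch = problem.setup.n_channels
    bbar2 = normalized_mean_square(problem.spec.waveform, problem.spec.tr)
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(nch) / nch)
    a = np.abs(problem.setup.sensitivities[:, problem.region].T @ phases)
    a_eff = a * np.sqrt(n_subpulses * bbar2)
    beta = problem.beta_vector()
    return float(np.dot(a_eff, beta) / np.dot(a_eff, a_eff))


def mls_shim_reference(
    problem: DesignProblem,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-12,
) -> WeightSet:
    """Independent variable-exchange MLS shim solver (Nsp = 1 only).

    Alternates a phase-target update z(r) = phase of the combined field
    with an unconstrained complex least-squares solve, then rescales into
    the feasible set; used solely as an oracle against
    ``design_push(n_subpulses=1)``.
    """
    if problem.spec.n_subpulses != 1:
        raise ValueError("the MLS reference is defined for a single sub-pulse")
    spec = problem.spec
    setup = problem.setup
    bbar2 = normalized_mean_square(spec.waveform, spec.tr)
    s = setup.sensitivities[:, problem.region].T * np.sqrt(bbar2)  # (Nvox, Nch)
    beta = problem.beta_vector()
    rng = np.random.default_rng(seed)

    def solve_from(phase0: np.ndarray) -> tuple[float, np.ndarray]:
        z = np.exp(1j * phase0)
        w = np.zeros(setup.n_channels, dtype=complex)
        last = np.inf
        for _ in range(max_iter):
            w, *_ = np.linalg.lstsq(s, beta * z, rcond=None)
            field = s @ w
            scale = max_feasible_scale(
                WeightSet(w[None, :]),
                problem.vops,
                problem.limits,
                spec.waveform,
                spec.tr,
            )
            if scale < 1.0:
                w = w * scale
                field = field * scale
            cost = float(np.sum((np.abs(field) - beta) ** 2))
            z = np.exp(1j * np.angle(np.where(field == 0, 1.0, field)))
            if abs(last - cost) < tol * max(cost, 1.0):
                break
            last = cost
        return cost, w

    best_cost, best_w = np.inf, None
    inits = [np.zeros(beta.size)] + [
        rng.uniform(0, 2 * np.pi, beta.size) for _ in range(n_starts - 1)
    ]
    for phase0 in inits:
        cost, w = solve_from(phase0)
        if cost < best_cost:
            best_cost, best_w = cost, w
    return WeightSet(canonicalize_weights(best_w[None, :]))
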