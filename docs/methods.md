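# Methods

## Physical model

**Two-pool system.** Tissue is modeled as a free-water pool (full Bloch
dynamics, magnetization `Mf = (Mxf, Myf, Mzf)`) exchanging with a semisolid
pool whose T2 is of order 10 μs, so it carries longitudinal magnetization
`Mzs` only.  Off-resonant RF saturates the semisolid at the average rate

    ⟨W⟩ = π γ² g(Δ, T2s) · ⟨B1+²⟩,      γ = 267.522 rad s⁻¹ μT⁻¹,

where g is the absorption lineshape in seconds and ⟨B1+²⟩ is the mean
squared RF amplitude.  For short-TR sequences the relevant average is over
the TR rather than the pulse duration (continuous-wave regime), which also
ties ⟨W⟩ directly to the SAR budget.  The package works throughout with the
TR-averaged root-mean-square, `B1rms = sqrt(⟨B1+²⟩_TR)`, in μT.

**Lineshapes.** Super-Lorentzian (tissue default), Gaussian and Lorentzian
are provided.  The super-Lorentzian is the standard angular integral over
fiber orientations,

    g(Δ) = sqrt(2/π) ∫₀^{π/2} sinθ · T2s/|3cos²θ−1| ·
           exp(−2 (2πΔ·T2s / (3cos²θ−1))²) dθ,

evaluated by adaptive quadrature with the magic angle listed as a
singular point.  All three forms follow the usual qMT normalization of
unit area over *angular* frequency (∫ g dω = 1, equivalently
∫ g df = 1/2π); with γ in rad/s/μT this makes ⟨W⟩ come out in s⁻¹.  The
integrand is near-singular at the magic angle for small offsets, so for
|Δ − shift| < 1 kHz the value is cubic-extrapolated from the [1, 2] kHz
band and flagged in the returned metadata; the shipped experiments operate
at 2 kHz offset with a −773 Hz line center (−2.6 ppm at 297.2 MHz), i.e.
an effective offset of 2.77 kHz where the integral is well behaved.

**Sub-pulse trains.** A saturation pulse is Nsp copies of one normalized
envelope b(t) (Gaussian by default: time-bandwidth product 2.27, duration
4 ms, 10 μs raster), each scaled per channel by a complex weight w_jp in
volts.  Envelope samples live on the midpoint grid t_k = (k+½)dt: this
keeps the envelope exactly symmetric about τ/2, makes n·dt equal the
duration exactly, and the midpoint rule on a smooth bell envelope is
superconvergent, so `b̄² = (1/TR)∫|b|²dt` agrees with adaptive quadrature
of the analytic envelope to better than 1e-8 relative at the default
raster.  The envelope is renormalized so its largest sample is exactly 1,
making the peak-voltage limit a direct bound on |w_jp|.  Because the total
B1rms² is a *sum over sub-pulses* of per-sub-pulse intensities, anything
that happens between sub-pulses — gradient blips in particular — cannot
change it.

**Sequence model.** The MT-weighted SPGR steady state is solved on
(Mzf, Mzs) per voxel: instantaneous excitation scales Mzf by cos α (ideal
spoiling, no RF-spoiling phase cycle), then relaxation, exchange and
saturation act continuously over the TR through the 2×2 generator; the
steady state is the fixed point of the affine per-TR map, solved in closed
form with a vectorized 2×2 matrix exponential.  The readout convention is
sin α × Mzf just after excitation; TE decay is omitted since it cancels in
MTR = 100·(Mref − Msat)/Mref.  The saturation pulse's rotation of free
water is neglected in the MTR simulation (the 2 kHz offset is far outside
the 567 Hz pulse bandwidth); `flip_angle_map` exists precisely to quantify
what that neglect hides.  Direct saturation by the excitation pulse is
likewise neglected.  A discrete per-TR saturation event
(`saturation_mode="discrete"`, factor exp(−W·TR) on Mzs) is available for
sensitivity checks; at TR = 22 ms it agrees with the continuous-wave
default to about a percent.

**Flip-angle maps.** The "flip angle" of a saturation train is evaluated
for spins resonant at the RF offset frequency, in the carrier frame: the
sub-pulses then act on-resonance, and only ΔB0 and the inter-pulse
gradient-blip phase rolls (antisymmetric about the FOV center) precess the
magnetization between sub-pulses.  Rotations are composed per hard-pulse
step (Rodrigues form, vectorized over voxels); the net rotation applied to
+z gives the flip angle.  This is the map that gradient blips scramble
while B1rms and MTR stay fixed — the executable demonstration that flip
angle is not a meaningful descriptor of semisolid saturation.

## The design problem

The optimizer minimizes `Σ_r (sqrt(Σ_p |Σ_j s_j(r) w_jp|² b̄² + ε) − β)²`
over the region of interest, with ε = 1e-12 μT² inside the square root so
the magnitude objective stays differentiable at field nulls.  Constraints:

* **Local SAR**: `b̄² Σ_p w_p† Q_v w_p ≤ 20 W/kg` at every virtual
  observation point (VOP) — Q_v are Hermitian PSD channel-space matrices,
  defined per V² of instantaneous drive and multiplied by the TR duty
  factor so SAR is TR-averaged exactly like B1rms.
* **Per-channel power**: `b̄²/Z · Σ_p |w_jp|² ≤ 24 W` with reference
  impedance Z = 50 Ω (configurable; the V→W conversion is a convention).
* **Peak voltage**: |w_jp| ≤ 207 V per sub-pulse and channel.

Weights are packed as stacked real/imaginary parts and solved with
sequential quadratic programming (scipy SLSQP) using analytic gradients
for the objective and every constraint (tolerance 1e-8, at most 500
iterations); SLSQP maintains its own quasi-Newton curvature estimate, so
no explicit Hessian is supplied.  Multi-start: start 1 is the CP-mode
solution split equally across sub-pulses; the rest draw uniform random
phases at half the voltage bound and are rescaled into the feasible set
(the paper-level protocol of 10 random starts is the default; the start
distribution itself is this package's choice).  The best feasible local
optimum wins; ties below 1e-10 break toward the lowest start index, so
reruns are bit-reproducible.  Returned solutions are audited against all
limits and, if the solver overshot by more than 1e-6 relative, scaled back
into the feasible set (all constraints shrink monotonically with a scalar
scale).  Each sub-pulse's weights are reported in the canonical gauge with
the first channel's phase zero.

Region semantics: for 2D designs the least-squares residual is restricted
to one axial slice, but SAR/power/voltage constraints are always global —
a scanner enforces them regardless of which slice is being optimized.
β may also be a per-voxel map; all shipped experiments use a uniform
scalar.

**Baselines.** CP mode fixes phases to exp(−i2π(j−1)/Nch) on every
sub-pulse and optimizes the single real amplitude over its feasible
interval (1-D bounded minimization; the unconstrained optimum has a closed
scalar-regression form used as a test oracle).  Once a constraint binds,
the amplitude sits on the boundary and the delivered B1rms caps — the
origin of the flat-then-rising NRMSE curve.  An independent
variable-exchange MLS shim solver (alternating phase-target update and
linear least squares, rescaled to feasibility) serves purely as a
cross-check for the single-sub-pulse case; it is never the design path.

**NRMSE convention.** `sqrt(mean((B1rms − β)²))/β`, normalized by the
target rather than the map mean: the design target is the natural scale,
and it makes the CP baseline's pre-cap NRMSE exactly constant in β.  Map
statistics use the population SD (divide by N).

## Synthetic scenarios

No measured B1+ maps ship with the package, so all end-to-end experiments
run on a synthetic testbed fully specified by (name, seed):

* **Coil fields**: 8 elements on a ring 1.25× the head radius around an
  elliptical (2D, 64×64, 240 mm FOV) or ellipsoidal (3D, 48×48×32, ring on
  the mid-volume plane) head surrogate.  Each element's magnitude decays
  exponentially (decay length 0.75× head radius), its phase advances 2π
  per 250 mm of distance, and channel j carries the azimuthal increment
  2π(j−1)/Nch so the CP combination is center-brightened (about 1.5–1.9×
  the mask-edge mean, the familiar 7T pattern).  On top of the ring model
  sit smooth random cosine ripples (35–140 mm wavelengths): a *shared*
  complex loading pattern (6% magnitude, 0.3 rad phase) modeling the
  head's dielectric loading common to all channels, plus a small 2%/0.05
  rad channel-specific term.  The shared ripple is deliberately the
  dominant fine structure: it is equally unfittable at any sub-pulse
  count, which reproduces the observed regime where two sub-pulses exhaust
  the exploitable map variability and a third adds nothing.
* **VOPs**: Hermitian PSD matrices built from a rank-1 random Gram factor
  (0.3 weight) plus a dominant random diagonal load — mirroring the global
  power-overestimation term that VOP compression algorithms add — then
  rescaled together so the CP drive delivering 1 μT mean B1rms produces a
  worst-VOP SAR of 10 W/kg, half the limit.  This calibration makes local
  SAR the binding constraint (CP caps near β ≈ 1.45 μT) with voltage and
  power far from active, as on the real system the surrogate emulates.
* **Tissue**: white matter, R1f = 0.4 s⁻¹, T2f = 60 ms, f = 0.1357,
  k = 32.79 s⁻¹ (kfs = k·f, ksf = k·(1−f)), R1s = 1.85 s⁻¹,
  super-Lorentzian with T2s = 9.6 μs centered at −773 Hz; shipped as a
  versioned JSON asset.  MTR simulations apply these parameters uniformly
  over the whole mask so the maps visualize saturation patterns, not
  anatomy.
* **Protocol timing**: one MTR map = 30 s saturated dummies + readout +
  10 s reference dummies + readout, with readout = encodes × averages ×
  TR.  The 2D protocol (220 × 4 × 22 ms) gives 78.72 s ≈ 1:19.  3D
  accelerated protocols are not modeled (their reference-line overhead is
  acquisition-specific).

Grid sizes are chosen so the full β sweep (20 targets × CP + PUSH-1/2/3,
10 starts each ≈ 620 solves) completes in about a minute on one CPU; the
optimizer's mathematics is resolution-independent, so nothing is learned
from an acquisition-size matrix that the 64×64 grid does not show.

**What the synthetic data do not emulate.** Real transmit maps carry
measurement noise, bias-correction residuals and anatomy-correlated
structure; real VOP matrices come from EM simulations of body models and
their normalization convention varies by vendor (the HDF5 loader records
the declared convention rather than assuming one).  Passing tests on the
synthetic scenarios demonstrates the correctness of the forward models and
the optimizer's behavior under the documented study conditions, not
performance numbers transferable to any particular coil or subject.

## Numerical choices and degenerate inputs

* 2×2 matrix exponentials and fixed points are evaluated in closed form
  (vectorized over voxels); the per-TR map's spectral radius is checked
  and a dedicated error is raised if it is not a contraction.
* Hard-pulse rotations use the Rodrigues formula per step; zero-field
  steps are identity by construction, and products are orthogonal with
  unit determinant to 1e-10 over hundreds of steps.
* The super-Lorentzian quadrature splits at the magic angle; the
  sub-1 kHz cubic extrapolation is fit on four nodes in [1, 2] kHz.
* Masks must be non-empty; empty regions, mismatched grids and NaNs
  inside the mask are rejected with specific exceptions.  Infeasibility of
  a *returned* design is impossible by construction (zero weights are
  always feasible); the solver raises only if every start fails audit.
* Mask erosion is per-axial-slice with a disk structuring element, with
  the image border treated as background.

## Known limitations

* Only the saturation-only design case is implemented: the excitation is
  always CP mode with a small uniform flip angle, and the joint
  flip-angle/saturation trade-off is out of scope.
* The continuous-wave TR-averaging of ⟨W⟩ is valid for short TR; for long
  TR the per-pulse average and discrete-event model should be preferred,
  and only a basic discrete variant is provided.
* Gradients *during* RF (which would engage the lineshape's frequency
  dependence spatially) are not modeled; blips between sub-pulses are.
* The semisolid's transverse dynamics, ihMT effects, diffusion, finite-TE
  decay and RF-spoiling imperfections are all outside the model.
* 3D designs inherit the z-axis limitation of circumferential coils: the
  optimizer cannot create degrees of freedom the coil does not have, and
  the 3D scenario reproduces the superior/inferior underdelivery.
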