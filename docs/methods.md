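# Methods

This note documents the models implemented in `dcecfm`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the known limitations.

## Tracer-kinetic layer

**Signal model.** The dynamic series is modeled as steady-state spoiled
gradient-echo (SPGR) signal, `S = M0 sin α (1 − E1)/(1 − cos α E1)` with
`E1 = exp(−TR·R1)` and `R1 = 1/T10 + r1·C`. The default acquisition profile
is TR/TE = 5.6/2.3 ms, flip angle 15°, ~12 s frame spacing — an abdominal
breath-hold DCE protocol. The TE-dependent T2* factor is constant across the
series and cancels in the inversion. Contrast relaxivity defaults to
r1 = 4.5 L·mmol⁻¹·s⁻¹ (gadobutrol-like at 3 T) and is configurable; the
baseline signal S0 is the mean of the first pre-bolus frames (default 3).
The inversion maps relative enhancement through the SPGR saturation curve
back to E1 and concentration; enhancement beyond the SPGR asymptote (possible
under noise) is clamped and flagged per sample rather than propagated as
NaN.

**Extended Tofts model.** The convolution
`∫ e^(−kep(t−τ)) Cp(τ) dτ` is evaluated with the exponential-kernel
recursion, which is *exact* when Cp is piecewise linear between samples.
This matters on coarse clinical sampling (10–15 s frames), where FFT or
trapezoid quadrature of the kernel would alias the bolus peak; it also makes
forward simulation and fitting numerically consistent. The recursion has a
guarded small-rate expansion (x < 1e-6) so kep → 0 degrades gracefully to
pure accumulation.

**Fitting.** Voxelwise bounded nonlinear least squares (trust-region
reflective) over K^trans ∈ [0, 5] min⁻¹, v_e ∈ (10⁻³, 1], v_p ∈ [0, 0.5],
multi-started from a fixed 3-point grid spanning slow/typical/fast kinetics;
the winner is the lowest residual, ties broken by the lower K^trans. This
makes the fit deterministic — repeated fits return bit-identical results.
Non-convergent voxels carry NaN sentinels and a `converged=False` flag, never
silent zeros. kep is always reported as K^trans/v_e.

**Flux model.** `v_e dCe/dt = (PS/V)(Cp − Ce) + (Jv/V)(1 − σT) Cp`, with the
convective term carrying the plasma concentration (the flux J_v transports
plasma at concentration Cp, attenuated by 1 − σT). Its solution is again an
exponential-kernel convolution, so the same exact recursion is reused. The
EES curve Ce is derived algebraically from the tissue curve via
`Ce = (Ct − vp·Cp)/ve` using the extended-Tofts estimates, and PS/V, Jv/V
are then fit with v_e held fixed. A joint re-fit of v_e was considered and
rejected: the observable Ce depends only on the decay rate PS/(V·v_e) and an
amplitude, so (v_e, PS/V, Jv/V) are structurally unidentifiable from one
curve — fixing v_e from the tracer-kinetic fit is the only well-posed
option. σT is taken from the tissue constants (0.82 in tumor), not fitted.
A zero AIF leaves both rates unidentifiable and is rejected.

**L_p rescaling.** `Lp(S/V) = Lp,0·(S/V)·(Jv/V)/⟨Jv/V⟩` with the mean over
the tumor mask, using the literature Lp,0 = 2.1e-11 m Pa⁻¹ s⁻¹ and
S/V = 2e4 m⁻¹. The construction preserves the tumor mean exactly, so the
rescaled field only redistributes — never inflates — total filtration
capacity.

## Domain construction

The ROI mask and K^trans map are resliced to 1 mm isotropic voxels
(nearest-neighbor for labels; mask-weighted trilinear for K^trans so
out-of-tumor zeros do not bleed into the rim), and the tumor is dilated with
a *spherical* structuring element of radius 10 voxels — implemented via the
Euclidean distance transform, so the margin is isotropic rather than
cube-shaped. Dilation runs after reslicing, giving "10 voxels" the fixed
physical meaning of 10 mm; the radius is configurable for protocols where
the margin is defined in native pixels. The grid is padded automatically so
the margin always fits. K^trans is undefined outside the tumor: the normal
shell uses normal-tissue constants with scaling factor 1.

Surfaces are triangulated by marching cubes at iso-level 0.5 (voxel-center
coordinate convention) and exported as binary STL for provenance and
interchange; a single-voxel mask cannot support a marching-cubes surface and
is emitted as a flagged voxel-sized box. `voxelize_surface` closes the
round-trip for validation (Dice ≥ 0.95 on spheres).

## Pressure solve

The stationary continuity equation with Starling source and lymphatic sink
is discretized with a 7-point finite-difference stencil on the labeled voxel
domain. Finite differences were chosen over tetrahedral FEM deliberately:
the domain is voxel-native, the operator is an isotropic reaction–diffusion
form, and the discrete solution can be audited voxel-by-voxel against 1-D
oracles. Face conductivities use the harmonic mean of K_H, which preserves
flux continuity across the tumor/normal interface where K_H jumps by 5×.
The outer no-flux (homogeneous Neumann) condition sits on the dilation
surface; with sources and sinks present the system matrix is symmetric
positive definite and is solved by diagonally preconditioned conjugate
gradients to a relative residual of 1e-10 (deterministic; sparse-direct
fallback if CG stalls). If every source and sink conductance vanishes the
Neumann problem is singular and the solve is rejected with a diagnosis
rather than returning an arbitrary constant.

Internally everything is SI (Pa, m, s). K^trans enters the equation only as
the dimensionless ratio K^trans/⟨K^trans⟩ (arithmetic mean over tumor
voxels), so its stored unit (min⁻¹) never needs conversion there. Three
source-scaling modes exist: `ktrans_scaling` (default; constant Lp·S/V
modulated by normalized K^trans), `lp_field` (the rescaled Jv/V map), and
`both` (their product). The default follows the continuity equation as
formulated; the alternatives support sensitivity analyses.

Validation anchors, all enforced in the test suite:

- **Equilibrium limit** — an all-tumor domain with no sink must relax to
  p_V − σT(π_V − π_i) = 2759.2 Pa (< 0.1% error; the solve is exact to
  rounding).
- **Radial oracle** — a 10 mm spherical tumor with shell solved on a 64³
  grid agrees with an independent 1-D spherically symmetric finite-volume
  solve (0.02 mm cells) to < 2% relative L2.
- **Conservation** — the volume-integrated source minus sink vanishes to
  < 1e-6 of the gross source (reached at ~1e-12 in practice).
- **Maximum principle, plateau, sharp falloff** — pressure stays between
  the tissue equilibrium pressures (≈ 187.5 Pa mixed-normal, 2759.2 Pa
  tumor); for R√(Lp(S/V)/K_H) ≥ 10 the core is within 1% of equilibrium;
  over half the core-to-far-field drop occurs within 5 mm of the rim.
- **Grid convergence** — halving the voxel size moves the tumor-mean
  pressure by < 1%.

The Darcy velocity u = −K_H ∇p_i uses central differences on interior
voxels and one-sided differences at the domain surface; the speed map peaks
in the tumor-rim shell, reproducing the expected exudate-flow geometry.

## Synthetic data

Phantoms compose the extended-Tofts forward model with the SPGR signal
equation on ellipsoidal tumors in a uniform background. The AIF is a linear
bolus ramp (default onset 30 s, rise 6 s, peak 6 mM) followed by a
bi-exponential washout (rates 0.02 and 0.002 s⁻¹, weights 0.8/0.2) — an
aortic-shaped curve with configurable parameters, since patient AIFs are
measured, not published, in this setting. Tumor K^trans is radially
modulated (core-elevated, amplitude 0.3) and renormalized so the tumor mean
equals the requested value exactly. Noise is additive Gaussian on the
magnitude signal, parameterized as a fraction of baseline (SNR 20 ↔ 0.05).

Cohorts default to the study conditions this package emulates: nine
subjects, tumor volumes log-uniform over 1.08–68.53 cm³ (right-skewed, as
clinical volumes are), per-exam multiplicative K^trans effects
(1.0, 1.93, 1.36) equal to the ratios of the reported cohort means — an
emulation of the observed treatment response, not ground truth — with one
subject missing the pre-treatment exam and another the first post-fraction
exam (N = 8, 8, 9). Sampling is uniform at < 15 s by default; an explicit
frame-time table (`PhantomSpec.frame_times_s`) can emulate the gap structure
of a multi-breath-hold acquisition, which is otherwise unspecified. The
exponential-kernel recursion is exact on any monotone timebase, so
non-uniform sampling needs no special handling downstream.

What the phantoms do *not* emulate: Rician noise statistics, B1/flip-angle
inhomogeneity, motion and breath-hold misregistration, k-space artifacts,
realistic tumor shapes, or spatial noise correlation. Passing tests
therefore demonstrate correctness of the estimators and solver under the
stated forward models, not robustness to every clinical confound.

## Statistics

"Wilcoxon" comparisons between exams are the two-sample Mann–Whitney
rank-sum form — with missing exams the samples are unpaired — two-sided,
with the exact null distribution for groups of ≤ 10 without ties and the
normal approximation otherwise. The exact distribution is computed once via
the Gaussian-binomial recursion and matches full enumeration for all group
sizes ≤ 6 (tested). Spearman ρ uses mid-ranks; categories are assigned on
|ρ| with boundaries closed downward: [0, 0.3] weak, (0.3, 0.7] moderate,
(0.7, 1] strong (the source bands have gaps; boundary values join the lower
band). No multiple-testing correction is applied, and the report footer
says so. Constant inputs leave ρ undefined and flagged.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class single
core: 64³ solver grids (~33k unknowns, < 1 s), 150-point 2 s-sampled curves
for recovery checks, 50 replicates at SNR 20, 10⁴ null simulations for
rank-sum calibration, and 4-subject demonstration cohorts with ROI-mean
fitting. Larger cohorts, full-range volumes and voxelwise fitting use the
same code paths and scale linearly.

## Known limitations

- No poroelastic solid stress, vessel-compression feedback or transient
  pressure dynamics; the solve is stationary.
- K_H is a literature constant per tissue class; treatment effects on ECM
  hydraulics are not modeled.
- The FXR (shutter-speed) signal model and B1 correction are out of scope.
- Exams are analyzed independently; no inter-timepoint registration.
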