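# Methods

`thermobrachy` plans simultaneous high-dose-rate brachytherapy (HDR-BT)
and interstitial hyperthermia (IHT) delivered through the same implanted
dual-electrode applicators.  This note documents the models, their
assumptions, the numerical choices, and what the synthetic phantom does
and does not represent.

## Voxel tissue model and synthetic phantom

All computations run on a regular voxel raster (default 64³ voxels at
2 mm; world coordinates in mm, voxel values at voxel centers).  Each
voxel carries one tissue label; the bundled property table gives, per
tissue, the mass density ρ (kg/m³), the electrical conductivity σ and
relative permittivity ε_r at the 27 MHz operating frequency, the
specific heat c (J/kg/K), the thermal conductivity k (W/m/K), and the
perfusion ω (ml/kg/min, converted internally to m³ kg⁻¹ s⁻¹ by
×10⁻⁶/60).  Blood parameters default to T_b = 37 °C, ρ_b = 1050 kg/m³,
c_b = 3617 J/kg/K (standard reference values; they enter only through
the perfusion sink product ρ_b c_b ρ ω).

The synthetic pelvic phantom stands in for segmented planning CT data:
an ellipsoidal prostate (default semi-axes 22/19/20 mm, ≈35 cc) with a
coaxial 3 mm-radius urethra, a posterior rectum cylinder with an air
lumen, a superior bladder, lateral bone cylinders, and a fat rim in a
muscle background.  Applicators are straight needles parallel to the
cranio-caudal axis placed on a 5 mm template grid inside the prostate
cross-section with a clearance zone around the urethra; positions are
chosen by greedy farthest-point selection starting from the most
peripheral node (mimicking the peripheral loading of clinical
implants) and jittered by a seeded ±0.5 mm placement uncertainty.
Each applicator carries a distal and a proximal 20 mm electrode
separated by a 5 mm gap, centered on the mid-gland.  Electrodes are
rasterized as the voxels whose centers fall inside the electrode
cylinder, with the capture radius widened to half the voxel diagonal so
1 mm-radius electrodes stay representable on 2 mm grids.

What the phantom does *not* emulate: real gland shapes and
inter-patient anatomical variation, needle curvature, intra-prostatic
heterogeneity, rectal filling variation, and CT-derived tissue
boundaries.  Passing tests on the phantom therefore demonstrate the
correctness and internal consistency of the planning chain under
controlled geometry, not clinical dosimetric accuracy for any patient.

## Electroquasistatic solver

At 27 MHz the wavelength far exceeds the domain, so each electrode's
complex potential satisfies the electroquasistatic equation
∇·((σ + j2πf ε)∇V_i) = 0 with the driven electrode at 1 V and, by
convention, all other electrodes and the outer boundary grounded (the
return-path configuration of the multi-channel system is not uniquely
defined by the hardware description; grounding the inactive electrodes
yields a linear basis consistent with field superposition).  The
discretization is flux-conservative finite differences with
harmonic-mean face admittances; faces to zero-conductivity material are
insulating by construction of the harmonic mean.  The complex-symmetric
system is solved with a Jacobi-preconditioned conjugate-orthogonal CG
(COCG) to a relative residual of 1e−8 (configurable); the system matrix
is shared by all electrodes, so only the right-hand side changes per
solve.  E-fields are central differences of the potential (one-sided at
the boundary), and the power density of an amplitude vector v is the
coherent quadratic form P = σ|Σ v_i E_i|²/2, cross terms included.

The sub-voxel Parylene coating of the applicators is not resolved at
the default 2 mm spacing; the applicator-dielectric material is in the
property table for explicit coating voxels on finer grids.

## Bioheat solver and temperature superposition

Tissue temperature follows the Pennes bioheat equation.  All planning
quantities refer to a ~1 h heating session, long compared with the
perfusion time constant ρc/(ρ_b c_b ρ ω) (≈2.5 min in prostate), so the
solver drops the transient term and solves the steady elevation
equation ∇·(k∇ΔT) − ρ_b c_b ρ ω ΔT + P = 0 with ΔT = 0 on the domain
boundary.  Solving for the elevation above the 37 °C pre-heating
equilibrium makes the metabolic heat term cancel.  Internal air voxels
are excluded from the stencil with insulating faces (no conduction
through the rectal lumen).  The operator is symmetric positive
definite and is solved with Jacobi-preconditioned CG (rtol 1e−8); it is
assembled once per model and reused for all electrodes.

The optimizer never solves a PDE: per-electrode unit-amplitude
elevations ΔT_i (driven by the diagonal powers P_i = σ|E_i|²/2) are
precomputed, and a candidate drive is evaluated as
T = Σ |v_i|² ΔT_i + T_b.  This neglects the off-diagonal (interference)
power terms.  The package validates that approximation against a fully
coupled reference: the total power of the same drive, cross terms
included, feeds one bioheat solve, and the two temperature elevations
are compared by 3D γ-index analysis at 5 %/0.5 mm criteria.

**Drive-phase model.**  The multi-channel RF system controls electrode
*amplitudes*; the relative phases of the channels are not a planning
variable.  The superposition is phase-blind by construction.  For the
coupled reference the package draws a seeded random phase per channel
(a frozen snapshot of an uncontrolled coherent drive) — the most
conservative physically motivated choice.  An in-phase drive of all
electrodes is *not* representative: with a common phase the combined
field between same-potential neighbors collapses and per-electrode
superposition (of any flavor) breaks down, which is precisely why
multi-electrode interstitial systems avoid coherent simultaneous
drive.  On the default phantom the measured γ(5 %/0.5 mm) passing rate
in the analysis region (reference elevation ≥ 10 % of maximum, global
normalization to the maximum reference elevation, search radius 3×DTA,
search step DTA/2 by trilinear subsampling) is ≈90 % and varies
≈82–95 % with the phase snapshot; disagreement concentrates at the
heating peaks where snapshot interference is strongest.  Under a
phase-drifting or multiplexed drive the time-averaged power has no
cross terms and the superposition becomes exact.

## Brachytherapy dose

The absorbed dose is a sum of TG-43-style point-source kernels over the
dwell positions: D(x) = Σ t·K·(r₀/r)²·g(r)·φ_an with r₀ = 10 mm, g ≡ 1
and φ_an ≡ 1 by default (a generic ¹⁹²Ir-like radial polynomial preset
is available; line-source tables are out of scope).  The near-field
singularity is capped at half the voxel diagonal.  Dwell candidates
step 2.5 mm along each applicator inside the target extent (+3 mm).

Clinical plans come from inverse planning plus manual fine-tuning; the
package instead ships a surrogate planner adequate for phantoms:
nonnegative least squares fits dwell weights to the 13.5 Gy
prescription at prostate-surface sample points, then a uniform rescale
sets the target coverage to V₁₀₀ = 96.5 % (clinical plans carry
headroom above the ≥95 % protocol objective).  Dose reduction studies
uniformly scale the resulting grid (70–95 %).

## Equivalent physical dose (TDLQ)

Simultaneous heat scales the linear-quadratic coefficients
exponentially between 37 °C and T_ref = 43 °C:
α(T)/α₃₇ = (α(T_ref)/α₃₇)^((T−37)/(T_ref−37)), likewise for β.  The
planning quantity is the equivalent physical dose normalized to the
physical dose,

    EQD_phys = [ (α/β)·r_α(T)·D + r_β(T)·D² ] / [ (α/β) + D ],

with α/β = 3 Gy for all tissues and the Lea-Catcheside factor G = 1
(high dose rate).  At 37 °C this is exactly D.  Bundled enhancement
ratios at 43 °C follow in vitro prostate carcinoma data: PC-3
(2.4, 6.8), DU-145 (0.8, 1.8), their arithmetic mean (1.6, 4.3), and
NONE (1, 1).  Above T_ref the same exponential extrapolates; the
optimizer's 47.5 °C ceiling bounds the range.  Normal tissue uses
either the tumor ratios (worst-case mode, the default for
optimization) or NONE (no-sensitization mode, the optimistic bound for
organ-at-risk reporting).  Absolute α₃₇/β₃₇ values are needed only for
survival fractions, never by the planning chain.

## Metrics and γ-index

V_x uses the ≥-threshold convention; D_xcc and the temperature
percentiles T₁₀/T₅₀/T₉₀ sort voxel values descending and interpolate
linearly on cumulative volume.  The γ-index takes a global
normalization (maximum of the reference by default), restricts analysis
to reference values above a configurable low cutoff (10 % of maximum),
and searches a spherical offset lattice around each evaluated voxel
with trilinear interpolation of the reference — required because the
0.5 mm distance criterion is finer than the grid.  Offsets are visited
in increasing distance so the search can terminate once the distance
penalty alone exceeds the running worst γ.

## Plan optimization

Constraint limits are taken from the *unscaled* BT-only plan: prostate
V₁₀₀ (high pass), urethra D₀.₁cc, rectum D₁cc, bladder D₁cc (low pass),
plus T_max ≤ 47.5 °C over all tissue voxels within 12 mm of any
electrode (the heating envelope; elevations outside it are negligible
by the perfusion penetration depth).  Violations contribute
PF_i = max(0, p_i(C_i−L_i)) weighted by W = 10³; scoring terms push the
urethra and rectum doses toward 0 (weight 1) and prostate V₁₅₀ toward
its 30 % soft limit (weight 0.01).  Scoring contributions are clipped
at zero (a metric below its goal scores 0) so the objective is exactly
zero when every constraint holds and every objective sits at its goal;
the printed form of the scoring term with a negative sign would reward
*raising* organ doses under minimization and is treated as a sign
misprint.

The objective is minimized over real nonnegative amplitudes by a
global-best particle swarm (40 particles, inertia 0.7298, cognitive =
social = 1.49618 — standard constriction values — velocity clamped to
20 % of the range, absorbing bounds, 300 iterations with early stop
after 50 stalled iterations, mandatory seed).  One particle starts at
v = 0 (the heating-off baseline).  Per-electrode amplitude bounds are
calibrated so a single electrode at full drive peaks at T_max.  Every
candidate evaluation reduces to dense matrix products of the
precomputed elevation basis restricted to the organ masks and heating
envelope (~10⁴ voxels), so a full optimization costs seconds.  Final
metrics are always recomputed from the best-ever amplitude vector.

## Problem sizes and reproducibility

Default study conditions: 64³ voxels at 2 mm, 18 applicators
(36 electrodes), one EM and one thermal solve per electrode (~2 s and
~1 s respectively), dose-scaling sweeps over 70–95 % in 5 % steps.
Every stochastic step (phantom jitter, validation drive, swarm) takes
an explicit seed, and fixed seeds reproduce results bit-for-bit.  The
per-electrode bases are cached on disk keyed by a content hash of the
model and solver settings.

## Known limitations

* The surrogate BT planner approximates, not reproduces, clinical
  inverse planning; absolute OAR dose levels on the phantom differ from
  clinical plans (the framework compares combined plans against the
  BT-only plan on the *same* geometry, which is the quantity of
  interest).
* The point-source kernel ignores source anisotropy and line-source
  geometry.
* Steady-state thermal modeling ignores transients, thermoregulation,
  temperature-dependent perfusion, and discrete vessels.
* The γ validation depends on the assumed drive-phase model (see
  above); a hardware-specific phase configuration would sharpen it.
* Dwell times and electrode amplitudes are optimized separately; joint
  optimization is out of scope.
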