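# Methods

## The metamorphosis model

`lesionmorph` registers a source image to a target with a metamorphosis:
a deformation and a pointwise intensity change estimated jointly. The
discrete path holds intensity frames `I_0 … I_T` and velocity fields
`v_0 … v_{T-1}` on `T` uniform steps of `[0, 1]`, and minimizes

    U(I, v) = Σ_t |v_t|²_V Δt + (1/σ²) Σ_t | (I_{t+1} − I_t)/Δt + ∇I_t · v_t |²_L2 Δt

The second term is the residual of the advection equation: where
transport by `v` cannot explain the observed intensity change, intensity
is created or destroyed at cost `1/σ²`. In the σ→∞ limit the solution is
purely photometric (zero velocity); as σ→0 the model approaches pure
diffeomorphic transport. Intensity change is essential for stroke
lesions, whose DWI signal genuinely appears and disappears rather than
merely moving.

Model assumptions: all images of a case live on one pre-aligned grid,
intensities are jointly min–max normalized to `[0, 1]` (the constants are
kept for unit-aware reporting), and the velocity field is smooth at the
scale of the V-norm kernel.

### Numerical realization

* **V-norm.** `v = K m` with `K` a Gaussian kernel of standard deviation
  `kernel_width_mm`, applied componentwise to a momentum field `m`;
  `|v|²_V = ⟨m, K m⟩ = ⟨m, v⟩`. The optimizer parametrizes `m`, so
  velocities are smooth by construction and the kinetic energy needs no
  kernel inversion. (`energy()` accepts externally built paths without
  momenta and recovers `m` by regularized Fourier deconvolution.)
* **Observation fitting.** The endpoint frames — and every intermediate
  observation in the multi-observation variant — are pinned to the data,
  so the estimated path fits each observation exactly; the advection
  residual absorbs the mismatch. Endpoint residuals are still measured
  and reported against `endpoint_tol` (default 1e-2), which matters for
  externally perturbed or truncated paths.
* **Optimization.** Alternating steepest descent with backtracking: one
  gradient step on all momenta (intensity path fixed), then one on the
  interior intensity frames (velocities fixed). Each accepted step must
  decrease `U`; a velocity step must additionally keep
  `det J(ϕ) > 0` everywhere, otherwise it is rejected and the step size
  halved (accepted steps grow the step size ×2). Iteration stops when
  the relative energy decrease falls below `tol` (default 1e-6) or at
  `max_iters` (default 500); non-convergence is returned, never hidden,
  and propagates as a warning into deformation maps and manifests. A
  non-finite energy aborts with diagnostics.
* **Discretization.** Central differences for `∇I`, forward differences
  in time, trilinear (bilinear in 2-D) interpolation with boundary
  clamping, forward-Euler integration of the flow `dϕ/dt = v(ϕ)`.
  Velocities are piecewise constant in time. All operators are
  dimension-generic; 2-D grids are first-class so tests and studies run
  quickly.
* **Defaults.** `σ = 0.05` weights fidelity strongly enough that
  boundary motion is explained geometrically. `kernel_width_mm = 2`
  matches the localization needed to resolve expansion and contraction
  of adjacent lesion regions; recovery of a coherent bulk translation
  (a different regime) benefits from a wider kernel, e.g. 6 mm, as used
  in the translation-recovery tests. Both are ordinary config knobs.

The estimated displacement under-recovers the true boundary shift by
design — part of the change is always attributed to the photometric
channel — so deformation magnitudes are interpreted comparatively
(within and across lesion regions), not as metric ground truth. The
translation fixture recovers a 2-voxel shift to ~0.1 voxel inside the
object with the wide-kernel settings.

## Deformation maps and highly dynamic areas

The total deformation magnitude is `Σ_t |v_t(x)|² Δt` (mm² per unit
path time) over the lesion; `speed = sqrt(magnitude)` is in mm per unit
path time. Path time is normalized per phase; a physical-time rescaling
is a presentation choice left to the caller since phase durations vary
per case.

The sign of deformation is the sign of the time-averaged projection of
`v_t` onto the outward lesion normal (the gradient of the signed
Euclidean distance to the mask boundary), with a dead band of 1e-6 mm
per unit time mapping numerically ambient voxels to 0. This extends the
intuitive boundary in/out notion to every voxel of the lesion.

Highly dynamic areas use strict mean/sd thresholds on speed computed
within the lesion: contraction keeps contracting voxels with
`speed > mean_c − sd_c`. For expansion two variants exist because the
printed rule is internally inconsistent (it thresholds expansion
against the *contraction* statistics):

* `corrected` (default): `speed > mean_e + sd_e` on the expansion
  field's own statistics;
* `as-printed`: `speed > mean_c + sd_c` using the contraction
  statistics.

Both are exposed; results record which was used. The rule is
scale-equivariant (scaling all velocities rescales speeds and
thresholds alike), and with zero spread the strict inequality selects
nothing. The analysis domain is the whole lesion mask by default; a
boundary-shell-only mode (mask minus its erosion) is available. In the
pipeline the lesion domain of a phase is the union of the phase-start
and phase-end masks so both the entering and the leaving voxels are
analysed; volumetric proportions are percentages of that union.

Note the contraction threshold `mean − sd` is deliberately permissive
(it keeps most contracting voxels); on the synthetic cohorts this
yields contracting proportions of tens of percent. The threshold is the
printed rule, not a tuned quantity.

## rMTT and the perfusion relation

The contralateral reference region is the mirror reflection of the
lesion mask about the midsagittal plane (default: the grid's central
sagittal index; reflection about index `m` maps `i → 2m − i` and is an
exact involution). rMTT divides each lesion voxel's MTT by the mean MTT
over the mirrored region, excluding non-finite or non-positive voxels
(counted in the output); an empty or non-positive normalizer is a hard
error. By construction the mean rMTT of the contralateral region is 1.

rMTT values of each deformation direction are binned (default width
0.01, the natural resolution of ratios spanning roughly 0.1–3);
per-bin mean speeds form the deformation–perfusion curve. The Gaussian
`a·exp(−(x−μ)²/2s²)` is fit by nonlinear least squares
(`scipy.optimize.curve_fit`, `a, s > 0`), initialized at the curve
maximum and the deformation-weighted mean/sd of the bins. The fit is
over binned means, unweighted by default (one point per rMTT value); a
`sqrt(count)`-weighted variant is a flag. RMSE is over bins, so a
noiseless Gaussian input gives RMSE ≤ 1e-8 and parameter recovery to
four decimals. The perfusion interval is reported as the ordered pair
`(μ − s, μ + s)` and never labelled upper/lower, since those labels are
ambiguous in the source material. Fits need ≥ 3 bins; fewer is an
explicit "not computable" record.

## The synthetic-data generator

The generator emulates the *structure* the analysis consumes, not MRI
physics:

* lesion components are ellipsoids with per-phase signed semi-axis
  growth (voxels); multi-component means ≥ 2 disconnected components
  with independent growth. Masks per timepoint follow analytically, so
  expansion/contraction ground truth is exact set algebra;
* images are a head-shaped phantom symmetric about the central sagittal
  plane (background 0.35, lesion 0.75, Gaussian-smoothed, additive
  clipped N(0, 0.02) noise), so mirror reflection is exact by
  construction;
* the true displacement field is radial per component: linear inside
  the start shape, Gaussian falloff outside — smooth and invertible at
  the configured growth magnitudes; it doubles as the oracle for
  registration tests via `apply_known_displacement`;
* MTT maps are a constant 4 s baseline with a hypoperfused halo around
  the lesion. Designated contracting/expanding zones — each truth ring
  dilated by 2 voxels into the lesion, i.e. the band the moving
  boundary sweeps — draw rMTT from configured Gaussians
  (defaults N(1.5, 0.15) for contraction, N(0.8, 0.15) for expansion;
  background N(1.2, 0.25)). Draws are rank-coupled to the local true
  displacement magnitude by default, so the fastest-deforming voxels
  carry the most central rMTT values: this reproduces the unimodal
  deformation-vs-perfusion relation the analysis is designed to fit.
  Setting `zone_halo_vox=0` and `couple_to_growth=False` gives plain
  i.i.d. draws on the bare rings;
* a fixed seed makes every volume byte-identical across runs; the
  subacute MTT map can be withheld to emulate cases lacking subacute
  perfusion.

What passing synthetic tests does **not** show: robustness to bias
fields, motion, partial-volume effects, non-mirror-symmetric anatomy,
misregistration between timepoints, or perfusion distributions that are
not unimodal. Real lesions also deform non-radially; the generator's
growth model is a controlled simplification.

## Study sizes and runtimes

The recovery study uses 20 cases on 64×64 grids with 10 timesteps —
comfortably resolving two lesion components and their dynamic rings
while keeping a full cohort run to about two minutes; 3-D volumes run
through identical code paths. Mean absolute error of the fitted rMTT
peaks against the generating means is ≤ 0.1 in both directions, cases
generated with well-separated means give disjoint `[p1, p2]` intervals,
and identically generated directions give overlapping intervals.

## Known limitations

* Deformation magnitudes are relative, not calibrated displacements
  (photometric absorption, see above).
* The forward-Euler flow is first-order; very large per-step
  displacements require more timesteps (Jacobian positivity is checked,
  and failures are explicit).
* The sign convention attributes motion through the lesion interior to
  whichever normal direction dominates on average; tangential motion
  maps to the dead band.
* Cohort statistics aggregate per-case fits; no between-case inference
  (correlation, hypothesis testing) is performed.
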