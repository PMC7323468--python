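# Methods

## Scope and design

`lumbarqmri` quantifies posterior lumbar muscle size, fat signal fraction,
and diffusion microstructure per vertebral level (L1–S1), and validates the
whole chain on a synthetic digital phantom.  The phantom is first-class
code, not a fixture: its ground truth defines the study conditions, and the
package's correctness claims are parameter-recovery statements against that
truth.

Two components use a model/results idiom: `DiffusionTensorModel.fit()`
returns a `TensorFitResult` carrying the tensor field and derived maps, and
`MuscleLevelANOVA.fit()` returns `AnovaResults` with effects, post hocs, and
a `summary()` table.  The remaining modules (phantom generation, Dixon
decomposition, ROI machinery, tractography) are pipeline stages with
functional interfaces.

## The phantom

### Geometry

Each muscle is a pair of mirrored elliptical tubes on a 0.625 × 0.625 × 1 mm
anatomical grid (multifidus medial with a 2:1 anteroposterior aspect ratio,
erector spinae lateral at 1.6:1), spanning six 24 mm axial slabs.  Slab
cross-sections are grown voxel by voxel in order of elliptical radius until
each muscle×level region holds exactly the voxel count implied by its target
volume, so per-level volumes are exact to within one voxel per side
(≤ 0.4 mm³ each).  Grids auto-size to the geometry plus a 3 mm margin; an
explicit grid that cannot hold the requested volumes raises a configuration
error.  Level boundaries are the six axial coordinates bounding the slabs
from below (the lower edge of S1 plus the five inter-vertebral midpoints);
level intervals are half-open [lower, upper), so each labeled voxel belongs
to exactly one level.

The grid sizes of clinical acquisitions cover a whole torso; the phantom
keeps the clinically meaningful parameters — the voxel sizes of the three
acquisitions (anatomy 0.625 × 0.625 × 1 mm, Dixon 1 × 1 × 1 mm, DWI
1.5 × 1.5 × 3 mm, 45 directions at b = 400 s/mm²) — and trims the empty
field of view.

### Ground-truth defaults

Only population aggregates are published for the cohort this phantom
emulates: mean volumes of 125.8 mL (erector spinae) and 54.0 mL
(multifidus); overall fat signal fractions 0.228 and 0.205; pooled fat
fraction rising from 0.188 at L1 to 0.338 at S1; roughly 13% of muscle
voxels above 0.45 fat fraction; and a qualitative level pattern (erector
spinae larger at L1–L4 with its peak at L3, multifidus larger at L5/S1;
multifidus fat fraction higher at L1–L3 and lower at L4–S1, both profiles
strictly increasing toward S1).  The per-level defaults in
`phantom.default_truth()` were derived once, by constraint algebra, as a
solution satisfying every one of those aggregates exactly; they are design
constants, not fitted quantities.  The volume defaults deliberately place
the erector spinae peak at L3 and its collapse below the iliac crest at
L4–S1.

Diffusion defaults use muscle-typical eigenvalue profiles,
λ = MD · (1.25, 0.95, 0.80), with mean diffusivity between 1.40 and
1.65 × 10⁻³ mm²/s: the erector spinae less restricted above L4, the
multifidus less restricted at L5/S1, and the largest diffusivities
mid-lumbar.  Fiber axes sit in the coronal plane at 20° (multifidus) and 5°
(erector spinae) from superior–inferior, mirrored across the midline — a
15° pennation difference that tractography must recover.

### Voxelwise fields

The fat-fraction field within each muscle×level region is a two-component
mixture: a bulk (intramuscular) Gaussian component (SD 0.05) whose mean is
set so the region mean equals the configured value, and a high-fat
epimuscular component (mean 0.70, SD 0.10) with the configured tail weight,
placed on the voxels nearest the muscle boundary (by Euclidean distance
transform) to form a shell.  Values are clipped to [0, 1] and the region
mean re-centered to within 5 × 10⁻⁴.  Tail weights (0.08–0.30, rising
toward S1 and volume-weighted across regions) put ≈ 13% of all muscle
voxels above a 0.45 fat fraction.

Tensors are piecewise constant per muscle×level region:
D = R diag(λ1, λ2, λ3) Rᵀ with R rotating the z-axis onto the region's
fiber axis.

Both fields are assigned natively on their measurement grids (fat on the
Dixon grid, tensors on the DWI grid), on the same nearest-neighbour
resampled label masks the ROI stage uses.  Interpolating a
coarsely-defined truth across region boundaries would mix background into
edge voxels and bias ROI means by more than the ±0.01 recovery contract;
defining truth at measurement resolution keeps the printed aggregates exact
targets while exercising the identical mask-resampling path used in
analysis.

### Signal simulation and noise

Dixon: IP = W + F and OP = W − F with F = S0·ff, W = S0·(1 − ff),
S0 = 100 inside the muscles and zero signal outside.  DWI: one b = 0 volume
plus S_i = S0 · exp(−b gᵢᵀ D gᵢ) over a deterministic
electrostatic-repulsion set of 45 directions (a Fibonacci-spiral start
relaxed under pairwise Coulomb forces with antipodal symmetry, fully
deterministic for a given count).

Noise is Rician — |signal + n₁ + i·n₂| with n ~ N(0, σ), σ = S0/SNR,
default SNR 40 — matching clinical magnitude images.  The out-of-phase
image is the one exception: its noiseless value is signed (W − F < 0 where
ff > 0.5), and a plain magnitude would alias every high-fat voxel to
1 − ff, which a swap-resolved fat–water reconstruction does not do.  The
simulator therefore returns a phase-corrected magnitude,
sign(OP) · |OP + n₁ + i·n₂|: identical to Rician noise away from the
water–fat crossover, sign-preserving at it.

Between-subject variability multiplies each subject's per-cell volume and
fat-fraction truth by 1 + cv·(z_subject + z_cell)/√2 (half shared per
subject, half independent per cell), default cv = 0.10 — a realistic
anthropometric spread.  Every stage draws from its own stream seeded by
(seed, subject, stage), so outputs are bit-reproducible and independent of
which contrasts are generated.

## Analysis choices

* **Dixon guard.** The fraction's denominator is guarded by
  10⁻⁶ × the 99th-percentile in-phase intensity; flagged voxels (air,
  background) are excluded from ROI means rather than contributing 0/0.
  Negative water or fat estimates (noise can push OP above IP) are clamped
  to zero, keeping the fraction in [0, 1].
* **Tensor fit.** Ordinary log-linear least squares by default; weighted
  least squares (weights ∝ signal²) behind a flag — at b = 400 and SNR ≥ 30
  the two differ by far less than the 5% ROI tolerance.  Multiple b = 0
  volumes are averaged.  Voxels with non-positive signals are marked
  invalid; negative eigenvalues are clamped to zero before computing
  metrics, preserving ROI sample size.  FA is defined 0 when all
  eigenvalues are equal (including all-zero), and the exactly-isotropic
  case returns exactly 0 rather than accumulated rounding noise.
* **ROI means** are computed on each map's native grid — no second
  interpolation — and volumes always come from the anatomical grid.
  Nearest-neighbour label resampling is deterministic, creates no new
  labels, and is idempotent.
* **Tractography** interpolates the six tensor components trilinearly and
  takes the principal eigenvector at the interpolated point, which
  sidesteps the per-voxel eigenvector sign ambiguity; the sign is aligned
  with the incoming direction at every step.  Defaults: 0.75 mm step (half
  the DWI in-plane voxel), 15° angular termination, FA floor 0.1, 10 mm
  minimum length.  Integration is bidirectional from every seed.
* **Statistics.** The omnibus tests are the standard univariate
  repeated-measures decomposition (each effect against its subject×factor
  interaction mean square), computed via `pingouin.rm_anova`; no sphericity
  correction by default (Greenhouse–Geisser behind a flag).  Post hocs are
  paired t-tests per level with Sidak m = 6 (the six levels are the natural
  comparison family), evaluated as −expm1(m·log1p(−p)) so tiny p-values
  keep precision and the adjusted value never drops below the raw one.
  Zero-variance tables report F = NaN with p = 1; exact ties in a post hoc
  get p = 1, exact separations p = 0.  Subjects with missing cells are
  dropped and recorded on the results object.
* **Covariate analysis.** The fat-fraction-covariate re-analysis centers
  metric and covariate within each muscle×level cell, pools a single slope,
  residualizes the metric, and re-runs the identical ANOVA — so a constant
  covariate reproduces the unadjusted F exactly, and design effects cannot
  leak into the slope.  The result records whether the significance pattern
  matches the unadjusted analysis.

## Validation and problem sizes

The test suite checks, among others: exact noiseless Dixon inversion
(≤ 10⁻¹²); exact noiseless tensor refit (≤ 10⁻¹⁰ relative, the log-linear
system being exactly determined); agreement of the tensor fit with an
independent nonlinear signal-domain least-squares oracle (≤ 10⁻⁸);
rotation invariance of FA/MD/RD; recovery of region-mean eigenvalues
within 5% and fat fractions within ±0.01 at SNR 40 with 10 subjects;
recovery of all printed aggregates on the default full-scale phantom; the
tractography angle contract on every emitted track and the 15° pennation
difference within ±2°; equality of the ANOVA F statistics with a
brute-force sums-of-squares oracle (≤ 10⁻⁸); and a null-phantom type-I
error within [0.03, 0.07] over 500 replicates at α = 0.05.

Most unit tests run on a 10%-volume phantom (identical fat fractions,
tensors, and level structure; only the tube cross-sections shrink), which
the geometry engine supports natively; the aggregate-recovery and
SNR-40 eigenvalue contracts use the full-scale phantom with 10 subjects.
The reproducibility script (`scripts/acceptance.py`) likewise uses the
full-scale, 10-subject, cv = 0, SNR 40 configuration; cv = 0 isolates
measurement error, since with subject variability the recovered aggregates
estimate the perturbed — not the configured — truth.

## What the phantom does and does not emulate

It reproduces: the three-grid acquisition layout and resampling chain,
level-dependent volumes and fat fractions with an epimuscular fat shell,
anisotropic level-dependent tensors with distinct muscle fiber axes,
magnitude-image noise, and between-subject variability.

It does not emulate: realistic muscle cross-sectional shapes or curved
fiber trajectories (regions are straight elliptical tubes with
piecewise-constant tensors), susceptibility distortion or its correction
(data are emitted pre-registered and undistorted), multi-echo fat–water
reconstruction physics (simulation starts at in/out-of-phase magnitudes),
partial-volume mixing between muscle and background signal, pulse-sequence
contrast (TR/TE), or motion/breathing artifacts.  Passing recovery tests
therefore demonstrates the correctness of the quantification chain under
the stated signal models — not robustness to distortion, segmentation
error, or reconstruction failure modes in clinical data.  Tractography
claims are limited to straight-field geometry: the pennation contract
checks mean orientations, not anatomically realistic fiber curvature.
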