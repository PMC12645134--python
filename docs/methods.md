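# Methods

`ctrsa` measures the migration of a knee implant relative to its bone from
pairs of serial CT volumes, and characterizes the *precision* of that
measurement with zero-motion rescan protocols on synthetic phantoms. This
note records the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## The measurement model

Implant migration between a baseline and a follow-up CT is modelled as a
proper rigid transform. The pipeline mirrors the clinical CT-RSA recipe:

1. **Object preparation** (baseline, and follow-up where needed).
   The implant (migrating object) is segmented at 2200 HU, the bone
   (reference object) at 200 HU; each is reduced to its largest connected
   component — the reproducible stand-in for manual removal of other
   structures — and dilated by one voxel (anisotropic in mm, matching the
   "one pixel" clinical convention). The axial slices covering the
   baseplate are excluded from the bone, and the implant is subtracted from
   the bone model so the two objects never overlap. An implant surface
   point model (the CAD stand-in) is registered to the implant segmentation
   and provides the measurement point set and the five labeled feature
   points (medial, lateral, anterior, posterior of the baseplate; stem tip).
2. **Initial alignment** via the align object (the prepared bone, or the
   whole-body outline thresholded at 3 HU with the scanner bench excluded).
   Centroids are matched, the three Euler angles are searched on a
   deterministic ±12° grid in 4° steps scored by masked normalized
   cross-correlation (NCC), and the best pose is refined by a short
   smoothed-image optimization. The published recipe suggests principal-axes
   matching here; long bones are too nearly rotationally symmetric for the
   in-plane axes to be stable, so the coarse grid search replaces it.
3. **Final registration**, independently for bone and implant, in one of
   two modes:
   * *gray-value mode*: maximizes NCC over the object's mask voxels,
     sampling the follow-up with cubic B-spline interpolation and
     optimizing the 6 pose parameters by L-BFGS with the analytic gradient,
     after a coarse stage on Gaussian-smoothed copies (capture range of a
     few mm / degrees). Deterministic by construction; no stochastic
     metric sampling.
   * *surface mode*: trimmed iterative-closest-point alignment of
     iso-surface point sets. Vertices come from marching cubes at the
     segmentation threshold, refined by two Newton steps along the local
     HU gradient (marching cubes interpolates the crossing linearly, which
     leaves phase-dependent offsets of flat faces around a tenth of a
     voxel). When target normals are available the rigid update minimizes
     point-to-plane residuals; point-to-point correspondences on
     grid-sampled surfaces carry the target's sampling pattern as a
     systematic bias on the order of the point spacing, far above the
     precision of interest. The worst 10% of matches are discarded each
     iteration.
4. **Relative motion**: `M = bone⁻¹ ∘ implant` in baseline world
   coordinates. Whole-scene repositioning cancels algebraically, which is
   what makes a zero-motion rescan series a valid precision experiment.
5. **Kinematics**: `M` is conjugated into the anatomical frame built from
   the baseline feature points (x medial, y proximal, z anterior;
   right-knee convention, left knees negate x). Reported outcomes are
   per-axis translations (mm) and extrinsic x-y-z Euler rotations
   (degrees, `R = Rz·Ry·Rx`), their Euclidean norms TT and TR, and maximum
   total point motion — MTPM, the largest displacement over the implant
   point set, plus its five-feature restriction. Per-axis values are
   Euler-convention dependent; TT, TR and MTPM are not, and comparisons
   across tools should prefer them.

Because the internals of commercial CT-RSA systems are unpublished, the
metric, optimizer and stopping rules above are this package's own documented
stand-ins, not claims of equivalence to any product. As a provisional
quality-control surrogate (none is established for CT-RSA), every
registration reports its final similarity, iteration count and convergence
flag, and these are carried into the per-pair results.

## The synthetic phantom

The phantom emulates a cadaver limb rescanned several times on one day: a
soft-tissue cylinder, a tibia-like bone, and a metal baseplate-plus-stem
implant, rigidly repositioned between scans (uniform per-axis translations
and Euler rotations within ±2 mm / ±2° by default, pivoting at the scene
center) while the implant stays fixed to the bone. Known migrations can be
injected for accuracy experiments.

Geometry choices that matter:

* The bone is a tapered *elliptical* cortical shell (axis ratio 0.8)
  around an *eccentric* marrow canal. A circular tube would make rotation
  about the bone axis unobservable to any registration; real tibias are
  distinctly non-circular.
* The implant stem is offset posteriorly from the plate center. A centered
  stem under a rectangular plate is 2-fold symmetric, which makes the
  model-to-segmentation fit ambiguous; real tibial trays are asymmetric.
* HU palette: air −1000, soft tissue 40, cortical bone 1200, metal 3000 —
  chosen so the clinical thresholds (200, 2200, 3 HU) separate the classes
  by construction.
* Default grid: 160×160×220 voxels at 0.390625 × 0.390625 × 0.625 mm (the
  clinical protocol spacing); a compact variant (96×96×128 at
  0.55×0.55×0.85 mm) is used for multi-series studies.

### Rendering accuracy is the load-bearing detail

Zero-motion precision of a few hundredths of a millimetre can only be
demonstrated if the renderer itself does not imprint pose-dependent
artifacts of that size. Three measures achieve this, found necessary in
that order:

1. **Off-lattice placement.** The scene is positioned a fixed sub-voxel
   fraction (0.37 voxels) away from the grid center so no flat face
   coincides exactly with a voxel-center plane; an exactly-on-lattice face
   gains or loses a whole voxel layer depending on floating-point rounding.
2. **Analytic occupancy instead of binary voxelization.** Each voxel is
   shaded from the signed distance to each shape through a Gaussian-CDF
   edge profile. Hard center-in/out voxelization leaves staircase/moiré
   patterns on flat faces that registration reads as apparent motion of
   several tenths of a voxel.
3. **Edge bandwidth at the grid Nyquist limit.** The edge scale is
   1.25 × the coarsest voxel spacing, leaving roughly 1% spectral energy at
   the Nyquist frequency, so even grid-aligned faces carry no coherent
   aliasing. A further Gaussian partial-volume blur of 0.5 voxels is
   applied on top. Adjacent solids of one material (stem and plate)
   overlap their interiors, because a min-union of signed distances whose
   boundaries merely touch produces a half-occupancy seam.

A consequence of the wide edge profile: a threshold placed asymmetrically
within an edge (200 HU sits at the 14% quantile of the soft→cortical
transition) biases mask boundaries outward by roughly half a voxel, so
threshold-mask voxel counts run a few percent above geometric truth — a
real CT effect as well. Similarly the 2200 HU implant iso-surface is biased
inward, so the fitted implant model carries a sub-voxel offset; the offset
is anatomy-covariant, identical in both scans of a pair, and cancels in
every between-scan comparison (asserted by test).

The bone reference subtracts the implant dilated by 4 voxels (not 1): the
implant's partial-volume tails reach a few voxels into surrounding tissue,
and any voxel they touch moves with the implant rather than the bone, which
under a true migration would bias the bone registration by up to a
millimetre. Surface mode analogously drops bone vertices within 4 mm of
the fitted implant model.

### Scanner degradation

Degradation is i.i.d. Gaussian HU noise plus bright/dark planar streaks of
Gaussian cross-section (σ 1.2 mm) through the metal centroid — a
controllable severity knob, not a physics simulation (no beam hardening,
reconstruction kernels, or MAR modelling). Two named profiles bracket a
better and a worse scanner: `ge-like` (noise 10 HU, 2 streaks, 60 HU
amplitude) and `siemens-like` (noise 25 HU, 6 streaks, 140 HU amplitude).
No published calibration for artifact severity exists; these values were
fixed once as the package's study conditions. Degradation-level studies use
none < ge-like < siemens-like and assert only the qualitative mechanism:
median zero-motion MTPM does not improve as degradation increases.

### What the phantom does not show

The phantom has no anatomical texture (trabecular structure, cortical
inhomogeneity), no femur or tantalum markers, perfect rigid repositioning,
and degradation far simpler than real metal artifacts. Passing the
zero-motion criteria therefore demonstrates the *internal* consistency and
numerical floor of the pipeline, not the precision attainable on cadaver or
patient data; the published cadaver figures (≈0.1 mm MTPM precision) are
not reproducible from synthetic scenes and are not targeted.

## Statistics

* **Precision** of a metric over the n(n−1)/2 pairs of an n-scan series:
  sample SD (n−1 denominator), reported with the ±1.96·SD interval
  conventional in the RSA literature. The pairs share scans and are not
  independent; the summaries describe spread and their intervals should be
  read with that caveat (surfaced in the module documentation).
* **Paired comparisons** (between modes, scanners, or against external
  outcome lists): mean difference (systematic error), SD of differences
  (random error), interval reported as mean ± 1.96·SD — which coincides
  with the Bland–Altman limits of agreement. Equivalence verdict against a
  minimal important difference (default MID 0.10 mm MTPM): *comparable* if
  the interval lies strictly inside (−MID, +MID); *not comparable* if the
  interval excludes zero and the contrast reaches the MID; otherwise
  *inconclusive*. A Shapiro–Wilk p-value is always reported but never
  switches the estimator; a configuration flag selects the nonparametric
  path (Wilcoxon signed-rank with a Hodges–Lehmann location estimate).
* **Balanced paired-design contrasts**: the linear mixed model with a
  factor fixed effect and pair-ID random intercept reduces, on balanced
  complete data, exactly to level means and mean within-pair differences
  with t-intervals on n−1 degrees of freedom. The closed form is
  implemented directly (no interaction term, single factor per call) and
  cross-checked in the test suite against a restricted-likelihood mixed
  model fit; unbalanced tables are rejected with a pointer to the plain
  paired comparison.

## Numerical choices and degenerate inputs

* Composition order: `(A @ B)(p) = A(B(p))`; transforms validate
  orthonormality and reject reflections.
* Gray-value optimization: L-BFGS, `ftol` 1e−13 / `gtol` 1e−9, iteration
  cap 200 per stage; rotation parameters are scaled by the mask's maximum
  lever arm so the optimizer sees comparable magnitudes. A line-search
  abort at a stationary point counts as convergence.
* ICP: update-norm tolerance 1e−7, cap 200 iterations; a residual that
  stops improving for five consecutive iterations (correspondence flips at
  the numerical floor) also counts as convergence. Degenerate point sets
  (rank < 3) are rejected.
* Model-fit initialization tests centroid matching under all 24 proper
  signed permutations of the principal axes plus the no-rotation
  hypothesis, refines the best three by ICP, and keeps the lowest residual
  — principal axes of small or near-symmetric objects are unstable in both
  order and sign.
* Largest-component ties break toward the lowest flat voxel index, with a
  warning. Euler decomposition raises near gimbal lock (|Ry| > 89°), far
  outside the physiological migration range.
* Identical baseline/follow-up volumes short-circuit the initial alignment
  to the identity.
* All randomness (pose sampling, noise, streaks) flows from explicit seeds
  through `numpy` seed sequences; rendering and registration are
  deterministic functions of their inputs.

## Problem sizes used by the shipped studies

The test suite and the acceptance script run: the zero-motion protocol on
a 7-pose noiseless series at the full default grid (21 pairs, both modes);
injected-migration recovery (0.5 mm, 1.0 mm, 1.0°) at the full grid; and
three degradation levels at the compact grid with 21 pairs each. These
sizes are the package's chosen study conditions; larger series scale
linearly in pairs.
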