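# Methods

## Problem and scope

`tumortex` quantifies whole-tumor heterogeneity on contrast-enhanced CT
and relates it to the pathologic grade of lung adenocarcinoma under the
IASLC/ATS/ERS predominant-pattern classification. The package covers the
full workflow: 54 per-tumor features (first-order, shape, GLCM, GLRLM),
a per-feature univariate screen, backward-elimination logistic models
for clinical and texture predictors, ROC analysis with the Youden
operating point, and the DeLong test for correlated AUCs. A phantom
generator supplies fully reproducible two-grade cohorts so every stage
is testable without patient data.

## Gray-level discretization

Texture matrices need integer gray levels. We use a fixed *bin count*
(default Ng = 64), equal-width over each tumor's observed HU range, with
the top edge inclusive. A fixed count keeps the GLCM size bounded and
features comparable across tumors of very different enhancement ranges.
The mapping is monotone in HU and invariant to adding a constant to all
ROI intensities; a constant ROI maps to level 1. Because the bins are
per-ROI, any *affine* rescaling of the intensities leaves the quantized
pattern — and hence every GLCM/GLRLM feature — unchanged; this matters
for the phantom design below.

## Feature definitions and conventions

* **First order (F1–F14).** Population (1/N) moments throughout;
  kurtosis is non-excess (Gaussian → 3); median of an even-count set is
  the mean of the central order statistics. Energy (F1) is the sum of
  squared intensities; histogram energy is Uniformity (F14), computed
  with Entropy (F2, bits, 0·log 0 ≡ 0) on the normalized Ng-bin
  histogram. Constant ROIs define skewness and kurtosis as 0 rather
  than dividing by zero.
* **Shape (F15–F22).** Volume is voxel count × voxel volume. Surface
  area comes from a marching-cubes isosurface at level 0.5 of the
  *mollified* binary indicator (Gaussian σ = 0.8 voxels): raw marching
  cubes on a 0/1 field triangulates the voxel staircase and
  overestimates a digital sphere's area by ~9% at every resolution,
  which caps sphericity near 0.92; mollification recovers sphere areas
  to <1% while reading sharp-edged polyhedra slightly low. A
  voxel-face-counting estimator (`estimator="faces"`) is kept for
  comparison with tools that use it (it is exact for axis-aligned
  boxes and ~50% high on spheres). Thin masks that smooth below the
  0.5 level fall back to the raw isosurface. Compactness 1 uses
  V/(√π·A^(2/3)) — the scale-variant form whose magnitude grows with
  tumor size. The maximum 3D diameter is the exact max pairwise
  distance between foreground voxel centers, computed on convex-hull
  surface voxels (identical result, much cheaper; the exhaustive pair
  scan remains as a test oracle). Because the estimator has ~1–2%
  discretization variance, sphericity values can marginally exceed 1
  for near-perfect digital spheres; convergence toward the continuum
  value with grid refinement is close but not strictly monotone.
* **GLCM (F23–F43).** Thirteen unique distance-1 offsets of the 3D
  26-neighborhood; symmetric accumulation (each in-mask pair counted in
  both orders); pairs never cross the mask boundary. Features are
  computed per direction on the normalized matrix, then averaged
  unweighted over non-empty directions — this ordering (features after
  matrices) keeps the averaged features exactly invariant under 90°
  rotations and mirror flips. Logs are base 2. Degenerate single-level
  ROIs define Correlation and IMC1 as 0. Offset distance is a config
  knob (default 1 voxel); matrices are built on the voxel lattice,
  ignoring anisotropy (documented limitation, matching common practice
  when no resampling is specified).
* **GLRLM (F44–F54).** Maximal same-level runs along the same 13
  directions, broken at the mask boundary; every foreground voxel lies
  in exactly one run per direction. Same per-direction-then-average
  convention as the GLCM.

## Phantom generator

Each phantom is a connected, approximately ellipsoidal blob on an air
background (−1000 HU). The boundary is a sphere whose radius is
perturbed by a smooth random field scaled by `lumpiness`; the
perturbation is clipped so the maximum caliper diameter stays within
15% of the request by construction.

ROI intensity = base enhancement (60 HU default) + two zero-mean
Gaussian components, each a Gaussian-smoothed white-noise field rescaled
to its target SD on the ROI:

* a *structural* field (default SD 40 HU, correlation length 4 mm)
  mimicking coarse vascular enhancement, and
* a *fine texture* field (default SD 15 HU, correlation length 1 mm)
  carrying the heterogeneity signal.

Intensities are rounded to integer HU, as CT stores them. The
`heterogeneity_contrast` knob multiplies the fine-field SD in the
high-grade class only. A single rescaled field cannot encode a texture
difference — per-ROI equal-width quantization removes amplitude — so
the designed group difference is the *ratio* of fine to coarse
amplitude, which monotonically lowers GLCM Homogeneity 1 (F33) and
raises fine-scale fragmentation as contrast grows. Per-patient
lognormal dispersion (σ = 0.2) on both SDs plus size and shape
variability create the within-class overlap a real cohort shows.

Cohort defaults mirror the published study population: 113 intermediate
+ 35 high grade; diameters ~N(30, 8) mm; never-smoker fractions 68/113
and 13/35 per class (with a deterministic exact-count mode so printed
2×2 tables are reproduced exactly); age, sex, stage and histologic
subtype drawn from the class-conditional frequencies of the cohort
tables, with grade always consistent with subtype under the grouping
rule. Identical spec + seed ⇒ bit-identical cohorts (per-patient
`SeedSequence` spawning).

What the phantoms do *not* emulate: lung anatomy, vasculature,
partial-volume effects, scanner noise spectra, or the enhancement
physiology that links texture to biology. Passing end-to-end tests
therefore demonstrates that the pipeline recovers a *designed*
heterogeneity difference of realistic magnitude — not that the
biological effect itself is reproduced.

## Statistical workflow

* **Grade grouping.** AIS/MIA → low; lepidic/acinar/papillary →
  intermediate; solid/micropapillary/colloid/invasive mucinous → high.
* **Univariate screen.** Shapiro–Wilk in each group at α = 0.05; both
  normal ⇒ two-sided Welch t-test (reported as mean ± SD), otherwise
  Mann–Whitney U (reported as pooled mean ranks). Welch rather than
  pooled-variance is deliberate with a 113:35 imbalance. The
  Mann–Whitney p is exact for small tie-free groups and
  tie-corrected-asymptotic otherwise. No multiplicity adjustment by
  default, mirroring the original reporting; Benjamini–Hochberg is
  available (`adjust="bh"`).
* **2×2 association.** Pearson chi-square without continuity correction
  when all expected cells ≥ 5, else two-sided Fisher. The method is
  always reported alongside p.
* **Logistic regression.** In-package Newton/IRLS: convergence at max
  |score| < 1e-8 or 100 iterations; Wald SEs from the inverse observed
  information; Wald 95% CIs exp(β ± 1.96·SE). Coefficients exceeding
  |β| > 20 raise a separation error; rank-deficient designs are
  rejected. On any 2×2-derived dataset the fit equals the closed-form
  log-odds-ratio and SE to 1e-8 (tested, plus a statsmodels
  cross-check).
* **Backward elimination.** Candidates enter at univariable p < 0.15;
  at each step the predictor with the largest Wald p above 0.05 is
  removed (ties toward the higher feature index); candidates are
  canonically ordered first so the final model is input-order
  invariant. Texture candidates are z-scored (per-SD odds ratios) and
  pre-filtered for redundancy — near-duplicates (|r| ≥ 0.98) and exact
  linear combinations (e.g. Range = Max − Min) are dropped in
  univariable-p priority order, guaranteeing a full-rank initial
  design. If a refit still separates, the worst offender by |β| in a
  weakly ridge-penalized fit is dropped with a warning.
* **Outcome coding.** Model coefficients are for *intermediate* grade
  (so the smoking OR is 0.391 as conventionally reported), while ROC
  sensitivity/specificity take *high* grade as the positive class
  (62.9%/60.2% on the published table). The two printed results are
  only jointly consistent under this split coding.
* **ROC / DeLong.** AUC is the tie-corrected concordance, identical to
  U/(n₁n₀); its CI uses the DeLong placement-value variance. The
  operating point maximizes Youden's J with ties resolved toward
  higher sensitivity. The DeLong comparison uses placement-value
  covariances with a two-sided normal p; identical scores short-circuit
  to ΔAUC = 0, p = 1.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence tests run 50 random 6³ ROIs per matrix family at
1e-10 relative tolerance against pure-Python brute-force references.
Sphere shape limits use diameters 20/40/80 voxels. The DeLong type-I
check uses 500 null replicates at n = 300. The end-to-end run uses the
full default cohort (113 + 35, heterogeneity contrast 2, exact smoking
counts) — about 20 s of compute — and reproduces the qualitative
finding: the homogeneity family (F33, F38) is flagged, and the texture
model's AUC exceeds the clinical model's with a small DeLong p. The
texture-model AUC on phantoms (~0.98) exceeds what was reported on
patients (~0.83); only the direction of the comparison, never the
magnitude, is treated as a target.

## Known limitations

* Absolute feature values depend on the (unknown) discretization and
  surface conventions of the original extraction tool; printed
  per-feature cohort means are therefore not comparable targets.
* Texture matrices ignore voxel anisotropy; shape features use
  physical spacing.
* The visual enhancement-heterogeneity scoring by radiologists is out
  of scope; only the kappa agreement statistic is implemented.
* The published cohort's smoking association p = 0.020 is not exactly
  recovered by Pearson (0.017) or Yates (0.028) chi-square on the
  printed counts; the package reports the method used next to p rather
  than forcing agreement.
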