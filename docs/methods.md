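# Methods

`tauradiomics` implements a tau-PET radiomics classification workflow on
common-space volumes: data-driven ROI definition, per-ROI texture feature
banks, two-stage feature selection, and linear-SVM evaluation under a
repeated cross-validation protocol, with SUVR and clinical-score comparator
models run through the identical harness. This note records the model, the
parameters that matter, the numerical choices, and the limits of what the
phantom cohorts can show.

## Preprocessing

Input volumes are assumed co-registered and spatially normalized to a
common template; the package performs only Gaussian smoothing and isotropic
resampling.

* Smoothing: per-axis Gaussian, kernel width given as FWHM in mm
  (`sigma = fwhm / (2*sqrt(2 ln 2)) / spacing`), default 8 mm. Boundary
  handling is nearest-edge replication (configurable through
  `gaussian_smooth(..., mode=...)`); total intensity is conserved away from
  the grid boundary.
* Resampling: trilinear interpolation onto an isotropic grid covering the
  same physical extent, default 2.0 mm (a typical normalized-PET grid; the
  value is configurable since sources rarely state it). Label maps use
  nearest-neighbor. Both grids share the first voxel center, so a volume
  already at the target spacing passes through unchanged.
* All internal computation is float64; files are written float32. PET and
  atlas entering one computation must share shape and affine exactly;
  mismatches raise instead of silently resampling.

## ROI definition

ROIs are defined on training subjects only:

1. voxelwise pooled-variance (Student) two-sample t test over the atlas
   foreground (Welch is available by flag); zero-variance voxels get p = 1;
2. Benjamini–Hochberg FDR at q = 0.01 on the in-mask p values;
3. cluster-extent filter: connected components of the rejection mask with
   strictly more than 500 voxels survive (18-connectivity by default,
   6/26 configurable);
4. atlas mapping: each atlas region overlapping the surviving mask by at
   least 64 voxels contributes one ROI whose mask is the intersection
   (significant voxels inside that region), not the whole region; a
   full-label mode is available. The 64-voxel floor keeps the texture
   matrices well populated.

If nothing survives (e.g. a null cohort), the pipeline falls back to
whole-atlas regions (reference region excluded) so downstream stages still
run; the fallback is logged and recorded in the provenance sidecar.

## Quantization and the 43-feature bank

Each ROI of each subject is quantized independently with the Lloyd-Max
algorithm (MSE-optimal scalar quantizer): centroids are bin conditional
means, boundaries are centroid midpoints, initialized from
equal-probability quantiles of the ROI intensities, iterated until the
relative MSE change is below 1e-6 (max 500 iterations; each iteration is
O(Ng log n) via prefix sums over the sorted sample). Default Ng = 64.
Constant ROIs yield a flagged single-level degenerate result.

Per ROI, 43 features: 3 histogram moments of the quantized levels
(biased variance, skewness, non-excess kurtosis), 9 GLCM, 13 GLRLM,
13 GLSZM and 5 NGTDM features. Conventions, chosen to match the printed
family counts of the classical MATLAB radiomics toolkits and documented in
`texture.py`:

* GLCM: Chebyshev-distance-1 co-occurrences over the 13 unique 3D
  directions merged into one symmetric matrix (not 13 per-direction feature
  averages); entropy in log2 with 0·log 0 := 0.
* GLRLM: maximal equal-level runs along the same 13 directions, merged;
  run percentage = runs / (voxels × directions).
* GLSZM: 26-connected equal-level zones (direction-free), computed in one
  connected-components pass over the equal-level adjacency graph.
* NGTDM: 26-neighborhood; coarseness and strength denominators carry a
  1e-6 guard.
* Degenerate inputs map to fixed constants (never NaN in output tables):
  single-level ROIs get zero skewness/kurtosis/contrast, GLCM energy 1,
  correlation 0, coarseness 1e6.

Because quantization is per-ROI and rank-preserving, all 43 features are
invariant to ROI translation and to global affine intensity rescaling of
the input volume; the test suite asserts both, and asserts equality with
independent brute-force enumerators (plain-Python pair/run/zone/neighbor
loops) to 1e-10 on random ROIs.

## Feature selection

Two stages, on training rows only, in fixed order:

1. Correlation redundancy filter: whenever two still-kept columns have
   |Pearson r| > 0.1, one of them (seeded coin) is dropped; the scan order
   is seeded-random, and the filter has its own RNG stream so
   classification seeds cannot perturb it.
2. Univariate screening: pooled-variance two-sided t test per remaining
   column, keep p < 0.005 strictly, no multiplicity correction.

If nothing passes stage 2, the single smallest-p survivor is retained so
the downstream model still has an input; on null data that feature is noise
and classification stays at chance.

**A caution on the 0.1 threshold.** At n training rows, the sampling SD of
Pearson r between *independent* columns is about 1/sqrt(n); with n ≈ 84 (a
60 + 60 cohort split 0.7/0.3) roughly a third of all independent column
pairs exceed 0.1 by chance, and any two genuinely discriminative columns
exceed it through the group structure itself. The filter therefore reduces
thousands of columns to a handful of survivors that are systematically the
*least* connected — i.e. the least informative — columns. This is a
property of the procedure at this operating point, not an implementation
artifact; the package implements it as printed and the evaluation reports
show its consequences (see Limitations).

## Classification harness

One code path serves the radiomics, SUVR and clinical models:

* 0.7/0.3 stratified train/validation split; an external-site cohort, when
  present, is wholly a test set.
* Covariates (age, sex) enter by training-fit linear residualization: each
  feature is regressed on [1, age, sex] over training rows and the fitted
  coefficients are applied unchanged to held-out rows. "append" and
  "ignore" modes are configurable alternatives.
* Features are z-scored with training-fit parameters.
* Linear SVM, C = 1, balanced class weights; stratified 5-fold CV repeated
  100 times with fresh fold assignments; repetition metrics are pooled
  out-of-fold predictions, reported mean ± SD.
* Validation/test metrics: each repetition's five fold models score the
  holdout with averaged decision values, giving a per-repetition holdout
  metric distribution and hence a mean ± SD there as well — the most
  parsimonious reading of holdout SDs reported alongside a repeated-CV
  protocol.
* AUC is the rank statistic (midrank ties), summarized as median and
  25–75% IQR over repetitions. The positive class (sensitivity) is always
  the patient group of the task, stated in the report header.

Comparators: SUVR(roi) = mean uptake in roi / mean uptake in the reference
region (cerebellum stand-in), no further selection; the clinical model is
MMSE alone.

Leakage discipline: the split is drawn first; ROI definition, selection,
covariate fits and scaler fits see training rows only; quantization is
per-subject and cannot mix subjects. A test perturbs validation volumes and
asserts every training-fit artifact is byte-identical.

## Phantom cohorts

The synthetic module emulates the statistical skeleton of a two-site
tau-PET study, not its anatomy or kinetics:

* Atlas: Voronoi cells of seeded points inside an ellipsoidal brain mask,
  default 64×64×64 voxels at 2 mm, 61 parcels (60 regions + one reference
  region, the parcel seeded lowest on the z axis, named `cerebellum_ref`).
* Subject volume = baseline uptake (5.0, arbitrary units) + unit-SD
  Gaussian random field (correlation length 4 mm) + a per-subject smooth
  low-frequency modulation field (SD 0.8 noise units, 16 mm correlation
  length). The modulation field models inter-subject regional uptake
  heterogeneity (delivery, perfusion, scanner gradients): it moves region
  means — including the reference, which is the classical weakness of SUVR
  quantification — while being too smooth to carry fine-scale texture.
* Patients: `mean_shift` (default 2.0 noise-SD units) added in the affected
  regions (default the first 12 region ids) and the noise correlation
  length stretched by `1 + texture_effect` (default 1.0, i.e. 4 mm → 8 mm)
  there; both scaled by a per-subject amplitude ~ N(1, 0.2) that also
  drives the tau-positivity and risk-allele carrier labels through logistic
  models (base rates 0.5). The reference region never receives group
  effects.
* External-site subjects get a global affine shift (×1.1 + 0.2) inside the
  brain, emulating a second scanner/tracer.
* MMSE: patients ~ N(24, 3), controls ~ N(28, 3), clipped to [0, 30] — a
  deliberately overlapping one-dimensional separator (~75% alone), so the
  clinical comparator is informative but clearly weaker than imaging.
* Everything is deterministic given the cohort seed; each volume depends
  only on (seed, subject index).

What the phantoms do **not** model: anatomy, tracer kinetics, scanner PSF,
partial-volume effects, off-target binding, motion. Passing tests on
phantoms therefore demonstrate the pipeline's statistical and numerical
correctness, not clinical performance.

## Problem sizes used in tests and the acceptance script

Repeated end-to-end suites run at desk scale, chosen once: null-safety uses
40³ grids with 21 regions at n = 30 + 30 over 20 seeds; effect recovery
uses the default 64³ grid with 61 regions at n = 60 + 60 over 5 seeds; the
effect-size-dial check uses 32³ grids with 11 regions. The acceptance
script mirrors these with 5 null seeds and 3 effect seeds (one with an
18 + 18 external site). Structural and oracle checks run at full fidelity.

## Known limitations

* The |r| > 0.1 redundancy filter is degenerate at small n (see above): on
  the phantom cohorts it reliably reduces ~1000+ columns to 1–4 survivors
  drawn from the least informative columns, so the radiomics model usually
  ends up a one-feature classifier near chance while the SUVR comparator —
  which skips selection — performs strongly. The qualitative model ranking
  radiomics ≥ SUVR ≥ clinical reported for real cohorts is not reproduced
  on phantoms at n = 60 + 60 for this reason; the evaluation harness makes
  the effect visible rather than papering over it.
* Cluster-extent thresholding uses voxel counts (not mm³); with 2 mm
  isotropic voxels a 500-voxel cluster is 4 mL.
* BH-FDR assumes exchangeable p values; spatial correlation of PET noise
  makes it conservative at the cluster stage, which the cluster-extent
  filter partially absorbs.
* Holdout mean ± SD reflects fold-assignment variability only; with a
  single fixed validation set the SD understates sampling variability of
  the subjects themselves.
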