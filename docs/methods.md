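# Methods

This note documents the models, numerical conventions and design choices of
the `pirads3` pipeline, in the order data flows through it.

## Problem setting

A PI-RADS 3 prostate lesion is an equivocal finding: biopsy shows clinically
significant cancer (csPCa, Gleason ≥ 3+4) in roughly a third of cases. The
pipeline builds and evaluates classifiers that predict the biopsy outcome
from (a) routinely available clinical variables — age, PSA, PSA density,
mean ADC in a 2D circular lesion ROI — and (b) radiomic texture features of
the manually segmented lesion on T2-weighted and ADC volumes. The intended
deliverable is a small, explainable model (PSA density + one T2 texture
feature + one ADC texture feature) whose every step is specified tightly
enough to be re-run elsewhere.

## Preprocessing

* **Normalization.** Three schemes are implemented as presets.
  `reference_roi` (the proposed protocol) divides all voxels by the mean
  intensity of a healthy peripheral-zone ROI, making the output scale-free
  (ROI mean ≡ 1). `mu3sigma` affinely maps [μ−3σ, μ+3σ] of the lesion VOI
  onto [0, 1] with clipping; the output range is a convention of this
  package since the source protocol does not name one. `zscore`
  standardizes the whole volume.
* **Resampling.** Cubic b-spline for intensities, nearest-neighbour for
  masks (re-binarized at 0.5). The output grid covers the input physical
  extent at the target spacing and shares the origin, so resampling onto
  the native spacing is the identity. Grid points beyond the last voxel
  centre clamp to the edge value; the spline prefilter uses mirror
  boundaries, so linear ramps are reproduced exactly only away from the
  volume edge (transient decaying as ≈0.27^k voxels).
* **Wavelet filtering.** One-level stationary (undecimated) separable 3D
  decomposition with the `coif1` pair, computed on the full resampled image
  *before* masking so lesion-boundary voxels see their true neighbourhood.
  Band letters are ordered slowest-to-fastest array axis: the first letter
  acts along z, the last along x; L = low-pass, H = high-pass. The library
  transform uses periodic boundary handling; odd dimensions are
  symmetrically padded to even length and cropped back. The inverse
  transform reconstructs the input to ~1e-10, which the tests verify.
* **Discretization.** Fixed bin number over the masked intensity range:
  label(v) = floor(N·(v−min)/(max−min)) + 1 with the maximum assigned N and
  constant ROIs collapsing to label 1. FBN makes all texture features
  invariant to affine intensity shifts; this exact invariance holds in
  floating point only away from bin-edge ties.

## Radiomic features

107 features per image (14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16
GLSZM, 14 GLDM, 5 NGTDM) follow the IBSI-consistent formulation used by the
common radiomics identifiers; shape is computed only on the original-grid
mask. Conventions that the identifiers leave open:

* **GLCM** — 13 unique 3D directions at Chebyshev distance 1; each
  directional matrix is symmetrized and normalized, then matrices are
  averaged with equal weight over directions that contain at least one pair
  (a 2-voxel ROI therefore averages only the directions that connect it).
  Degenerate single-level matrices return Correlation = MCC = 1 and
  Imc1 = Imc2 = 0.
* **GLRLM** — runs per direction with out-of-mask voxels breaking runs;
  features are computed per direction and averaged.
* **GLSZM** — zones are maximal 26-connected components of equal label;
  orientation-free.
* **GLDM** — α = 0 (exact label equality), distance-1 26-neighbourhood,
  dependence size = 1 + number of dependent neighbours (an isolated voxel
  has size 1).
* **NGTDM** — per-level absolute deviation from the 26-neighbour mean;
  voxels with no in-mask neighbour are excluded; Coarseness of a perfectly
  homogeneous ROI is capped at 1e6.
* **Shape** — surface area and volume from a marching-cubes mesh of the
  binary mask (voxel-face counting overestimates curved surfaces; the
  staircase mesh still overestimates slightly, so the sphericity of a
  digital ball approaches 1 from below as the radius grows). Axis lengths
  are 4·√λ of the voxel-centre covariance eigenvalues; maximum diameters
  use convex-hull vertices in physical coordinates.
* **First order** — population moments; kurtosis is not excess-corrected;
  Entropy/Uniformity use the preset's FBN histogram; zero-variance ROIs
  return 0 for skewness and kurtosis.

Features that cannot be computed on a degenerate ROI (e.g. a single-voxel
mask has no GLCM pairs) are emitted as NaN sentinels, logged, and excluded
from selection; nothing is silently dropped.

The mean-ADC measurement mimics the clinical 2D reading: on the axial slice
of maximal lesion area, the largest inscribed disc is found via the
in-plane Euclidean distance transform (ties broken toward the first maximal
pixel in scan order) and the mean ADC within that disc is returned. The
disc provably never exceeds the lesion margin.

## Stability selection

500 trials = 100 independent stratified 5-fold partitions of the 80
patients (positive counts per fold differ by at most 1, so 26 positives
give 5–6 per fold). Per trial, on the 64-patient training portion only:
two-sided Mann–Whitney p per feature (tie-corrected normal approximation
with continuity correction; exact enumeration for combined n ≤ 12, which
only matters for unit tests), then a greedy walk in ascending-p order
seeded by the smallest-p feature, admitting a feature with p ≤ 0.01 only if
its |Spearman ρ| (midrank-based) against every already-admitted feature is
below 0.5 on the training slice. Equal p-values break lexicographically by
name. The final pool ranks features by selection rate; the default rate
cutoff of 0.80 is configuration-exposed, since published high-stability
features sit in the 83–100% range.

## Model evaluation

Univariate models pick the cut-point maximizing J = sens + spec − 1 by
exhaustive search over midpoints of consecutive sorted unique training
values (± sentinels), in both orientations; ties break toward higher
sensitivity, then lower threshold, then the positive-above orientation.
Both published cut-point semantics are representable: "positive below
0.47" (T2 regularity) and "positive above 17" (ADC zone-size).

Multivariate families: linear discriminant, linear/quadratic/cubic SVM
(C = 1, poly coef0 = 1), decision tree (unlimited depth), KNN (k = 5) — the
six-family comparison set — plus random forest (depth 16, no feature
subsampling, min leaf 2, min split 2, ≤ 16 leaves, with SMOTE) and logistic
regression on z-normalized inputs for the two literature presets.
Hyperparameters the sources leave unstated are fixed, documented defaults
exposed in `ClassifierSpec`. Decision thresholds for the proposed-model
families are re-optimized by Youden on the training scores (class
imbalance is handled by threshold optimization rather than oversampling);
the literature presets keep their native decision rules. SMOTE (k = 5
minority neighbours, uniform interpolation, classes balanced exactly) is
applied strictly inside training portions; validation indices never enter
synthesis. Validation folds with a single class would contribute NaN to
the affected metric and are excluded from means with a logged count — with
stratification at the default sizes this cannot occur.

The final shareable model is trained on the whole cohort and serialized to
JSON with explicit per-feature weights, intercept, score threshold and
optional z-scoring statistics. Only families with an explicit linear score
(threshold, linear discriminant, logistic) are serializable; the shared
model is the trivariate linear discriminant, so this covers the intended
artifact while keeping reload bit-exact.

## Synthetic cohort generator

The generator is the package's stand-in for the private 80-patient cohort.
It reproduces the published population *marginals* and plants known class
effects so recovery can be tested; it does not emulate scanner physics,
bias fields, registration error, or inter-observer segmentation
variability, so passing tests demonstrate correctness of the pipeline's
statistics, not clinical performance on real images.

* **Clinical table.** Exactly 26/80 positive labels per seed. Age and mean
  ADC are truncated normals on the published ranges. PSA and PSA density
  are correlated log-normals (rank correlation 0.5); PSA moments match
  6.8/4.8 with clamping to [0.5, 29.6]. PSA density is a two-class
  log-normal mixture: the csPCa class is shifted by δ = 0.7 on the log
  scale, and (μ, σ) solve in closed form so the *mixture* has mean 0.15 and
  SD 0.15 before clamping to [0.01, 1.09] (clamp bias on the mean is below
  0.002). δ = 0.7 is a calibration constant, not an estimate: via the
  closed form it places a univariate Youden model in the mid-60s%/low-70s%
  sensitivity/specificity regime, the published operating point of PSA
  density alone. Prostate volume is derived as psa / psa_density so the
  ratio invariant holds exactly.
* **Image geometry.** 48×48×16 voxels at 0.5×0.5×3.0 mm (T2) and
  1.0×1.0×3.0 mm (ADC) — desk-scale but anisotropic like clinical
  acquisitions. One ellipsoidal lesion per patient, diameter uniform on
  9–13 mm (PI-RADS 3 lesions are typically about a centimetre; a narrow
  range also keeps the strong size-dependence of unnormalized zone counts
  from swamping class effects). A corner box of stationary background
  serves as the normalization ROI, always disjoint from the lesion.
* **Label-independent heterogeneity.** Every patient draws a personal T2
  random-field correlation length, fine-noise amplitude, ADC zone-seeding
  density and zone-value spread. This common-mode variance makes features
  of one family co-vary across patients — as they strongly do on clinical
  images — which is what lets the Spearman redundancy filter collapse each
  family to essentially one representative per trial.
* **T2 class effect** (`t2_regularity_shift`, default 260 intensity
  units). Every lesion contains a focal core (half the lesion diameter,
  random offset) whose contrast baseline is mild (gamma-distributed);
  csPCa adds a large extra signal drop. A markedly hypointense nodule is
  the classic csPCa appearance on T2, and quantitatively it creates large
  grey-level jumps and inflates the FBN range, lowering LLL-band GLCM
  InverseVariance. A naive alternative — shortening the random-field
  correlation length — was rejected because under FBN quantization and LLL
  smoothing that *raises* InverseVariance over the reachable roughness
  range (the response is non-monotone and the smoothing caps achievable
  roughness).
* **ADC class effect** (`adc_zone_heterogeneity`, default 1.0,
  multiplicative). csPCa lesions get denser Voronoi zone seeding (+0.16
  seeds per voxel) and scattered microfocus blobs (2.5% of voxels, ±2.5e-4
  mm²/s), producing finer zone fragmentation and hence higher GLSZM
  zone-size heterogeneity on the LLL band (visible in ZonePercentage,
  SizeZoneNonUniformity and the large-area emphasis features). Zone values
  centre on the patient's clinical mean ADC, keeping the image and the
  clinical table coherent.
* **Effect neutrality and determinism.** All three effect parameters are
  0-neutral: at zero effects the two classes are drawn from bitwise
  identical distributions (the same rng state yields voxelwise-identical
  volumes for either label). All randomness flows from the cohort seed
  through a `SeedSequence` split — child 0 for the clinical table, child
  i+1 for patient i's images — so a cohort is a pure function of
  (spec, seed).

Effect magnitudes were fixed once, by generating labelled image batches
and choosing values whose feature-level separations sit in the regime the
published selection rates (83–100%) imply; they are documented calibration
constants of the generator, not claims about tissue.

## Desk-scale run sizes

The default test and demonstration runs use the full 80-patient cohort and
all 500 selection/evaluation trials, with the radiomic candidate set
reduced to the families the proposed model draws from (T2-LLL GLCM,
ADC-LLL GLSZM, plus the four clinical variables, 44 candidates) — the full
958-feature extraction is exercised per patient but sweeping it through
500 × 44k univariate tests adds nothing to what the reduced set
demonstrates. Oracle-equivalence checks run on 100 random ROIs up to
5×5×3 voxels with up to 4 grey levels, where exhaustive enumeration is
feasible.

## Known limitations

* Absolute feature scales (e.g. the SizeZoneNonUniformity ≈ 17 cut-point)
  are not reproduced — only directions, rankings and the machinery are.
* The generator's negative class is a single population; benign
  sub-categories (GS 3+3, prostatitis, BPH) are not modelled separately.
* Transitional vs peripheral zone differences are not modelled.
* DWI is represented by its ADC stand-in; the literature preset that calls
  for b = 1500 DWI is evaluated on ADC and documented as such.
* N4 bias-field correction is out of scope; synthetic images are generated
  bias-free.
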