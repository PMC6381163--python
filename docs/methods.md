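# Methods

## Problem setting

The package predicts a binary nodal status (metastasis vs non-metastasis)
from the appearance of the primary breast mass on a single
contrast-enhanced MRI phase, the phase in which lesion–background contrast
is largest. The analysis chain is: normalize and resample the volume,
segment the mass by seeded region growing, extract a 58-dimensional
radiomic feature vector, reduce it by LASSO-logistic selection, evaluate
classifiers under stratified cross-validation, and express the final
logistic model as a points-based nomogram. Because the patient volumes
behind the original analysis are not publicly available, the package
evaluates the chain end to end on synthetic lesion phantoms whose
generative model is documented below; all quantitative results shipped with
the package are therefore statements about the method's behavior under
that generative model, not about patient data.

## Phantom generative model

Each subject is one lesion on a `64 × 64 × 16` voxel grid (the desk-scale
default; the 384² production in-plane size is a configuration option).

* **Shape.** A spiculated ellipsoid: in ellipsoid-normalized radial
  coordinates the boundary is `r ≤ 1 + a·sin(mθ)·sin(φ)` with `m = 6`
  angular lobes, strongest in the axial plane. In-plane radius is drawn
  uniformly from 4–7 voxels; the through-plane semi-axis is half the
  in-plane radius (breast masses are typically anisotropic with respect to
  slice thickness). `a = 0` gives a discrete ellipsoid.
* **Intensity.** Lesion voxels are `lesion mean + texture + noise`,
  background voxels `background mean + noise`, clipped to [0, 1]. Defaults:
  lesion mean 0.70, background 0.30, Gaussian noise SD 0.05. If clipping
  touches more than 20% of lesion voxels a warning is logged, since the
  nominal effect sizes are then distorted.
* **Texture.** A Gaussian random field: white noise smoothed with an
  isotropic Gaussian kernel of width `texture_correlation_length` (default
  1.2 voxels), then centered and scaled *over the lesion mask* to mean 0
  and SD `texture_contrast` (default 0.10). Centering matters: a small
  lesion contains only a few correlation lengths, so an uncentered field
  would shift the lesion's mean intensity by a large random offset and
  confound the intensity axis with the texture axis.
* **Class effects and subject variability.** Metastasis-class offsets
  (defaults): +0.08 lesion mean intensity, +0.05 texture contrast, +0.8
  correlation length, +0.6 voxels radius, +0.08 spiculation amplitude.
  Every axis also carries between-subject jitter (intensity SD 0.06,
  spiculation SD 0.06, contrast SD 0.03, correlation-length SD 0.3), so
  each offset is roughly 1–1.5 subject-level standard deviations. The point
  of this calibration is qualitative fidelity to the study design: each
  feature family carries real but imperfect signal, no single feature
  separates the classes, and the combination of morphology and texture
  outperforms either family alone. With all offsets zeroed
  (`class_effect={}`) the generator is an exact null.
* **Determinism.** Every subject's stream is spawned from the master seed
  as `SeedSequence(master_seed, spawn_key=(subject_index,))`; cohorts are
  bit-reproducible and parallelizable.

What the phantoms deliberately do **not** model: pharmacokinetic
enhancement curves (only one post-contrast-like phase is emulated), organ
anatomy and bias fields, scanner-specific noise spectra, and multi-lesion
subjects. Passing tests on phantoms therefore demonstrates correctness and
statistical sanity of the pipeline, not clinical performance.

## Segmentation

Region growing accepts the connected voxel set (6-connected by default)
within intensity tolerance `T` of a reference value, inside a rectangular
region of interest copied to all slices. Default `T = 0.25`, half the
nominal lesion–background contrast of the phantoms. Three reference
criteria are provided:

* `seed_window_median` (default): the median intensity of a 7×7×3 window
  centered on the seed. This is the deterministic analog of "the clicked
  voxel is representative of the bright core": a single voxel of a textured
  lesion is an unstable reference (its tolerance window can overlap the
  background and flood the mask), while the windowed median averages over
  several texture correlation lengths.
* `seed_value`: the seed voxel's own intensity (the classical definition).
* `running_mean`: candidates are compared against the running mean of the
  region grown so far, FIFO frontier in fixed axis order (deterministic).

Dice is defined as 1.0 when both masks are empty (logged). ICC is fixed to
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
computed from the ANOVA mean squares; an all-equal table is defined as
perfect agreement. "Independent segmentation groups" for the stability
analysis are emulated by perturbing the seed by ±1 voxel and `T` by ±10%.
Under that perturbation the size and location features are highly stable
(ICC ≈ 0.9–1.0) while a substantial subset of texture features is not:
their quantization bounds are the extremes of the in-mask intensities,
which move with the threshold. This is precisely the failure mode an
ICC-based stability filter exists to catch, and the filter's tests assert
that discrimination rather than a fixed pass rate.

## Feature definitions

The canonical 58-name registry lives in
`radln.features.FEATURE_REGISTRY` (name, family, formula sketch); the exact
formulas are frozen there and in the family functions. Conventions chosen
once and used everywhere:

* Quantization: equal-width bins over the in-mask [min, max]; 16 levels for
  the co-occurrence matrix, 256 for the other matrix families; a range at
  floating-point noise level counts as constant (all voxels level 0).
* Co-occurrence: distance 1, angles {0°, 45°, 90°, 135°}, symmetric pairs,
  counts summed over angles then normalized. Both pixels of a pair must be
  in-mask. The eight Haralick descriptors are energy, contrast,
  correlation, inverse difference moment, entropy, variance (sum of
  squares about the marginal mean), sum average and sum entropy.
* Run length: angles {0°, 90°}, features averaged over angles; runs are
  maximal stretches of equal level and are broken by mask gaps (Galloway's
  five descriptors).
* Gray-gradient: Sobel magnitude of the unquantized slice, gray at 256 and
  gradient at 16 levels; fifteen descriptors of the normalized joint
  histogram, with 0-based level weights for means/variances/correlation/
  inertia and `(s+1)²` weighting in the emphasis terms.
* Dependence matrix: Chebyshev distance 1 (8 neighbors), tolerance 0, and
  the interior convention — only pixels whose full neighborhood is in-mask
  are counted. The `k = 0` bucket uses weight 1 in the `k²` emphasis terms.
* Tamura: coarseness over window sizes `2^k, k ∈ 0..4` with shift equal to
  the window (ties resolved toward the smallest k, so a constant region has
  coarseness 1); contrast `σ/(μ₄/σ⁴)^{1/4}`; directionality as the
  resultant length of the doubled-angle 16-bin Sobel-orientation histogram
  over pixels with gradient magnitude above 1e-3 — a peaks-free
  concentration measure in [0, 1].
* Histogram: moments from the raw in-mask intensities (kurtosis is the
  excess kurtosis), energy/entropy from the 256-bin range-relative
  histogram.
* Degenerate inputs: 0·log 0 := 0 everywhere; correlation, skewness,
  kurtosis and Tamura contrast are defined as 0 at zero variance; all
  entropies are in bits.
* Morphology (16 descriptors) is computed on the maximum-area slice of the
  mask (largest connected piece if the 3D-connected mask splits in-plane
  there); texture families are computed on every slice meeting the
  family's precondition and averaged. A family computable on no slice
  flags the subject, which is excluded with a log message.

Every matrix family is verified in the test suite against brute-force
enumeration (explicit pair/run/neighbor loops sharing no code with the
implementation) on dozens of random masked images, and the descriptor
algebra against independent double-loop summation.

## Selection, evaluation, nomogram

* LASSO-logistic: objective `(1/n)·deviance + λ‖β‖₁`, intercept
  unpenalized, features standardized to population SD 1 inside each
  training fold (no leakage). Grid: 100 log-spaced λ from λ_max (closed
  form: all-zero coefficients, intercept = log-odds of the class balance)
  down to `10⁻⁴·λ_max`, or `10⁻²·λ_max` when p ≥ n. The path is
  warm-started; it stops early when the solver hits its iteration cap
  (quasi-separation near the unpenalized end) or the fit is essentially
  saturated (deviance ratio > 0.999), mirroring standard coordinate-descent
  practice. λ is chosen at minimum mean held-out binomial deviance over
  stratified 10-fold cross-validation (minimum criterion, not 1-SE), and
  the support comes from a full-data refit at that λ.
* Classifiers: SVM (RBF, C = 1, gamma = `scale`), KNN (k = 5, Euclidean,
  score = positive-neighbor fraction), LDA (posterior score). Metrics are
  pooled (micro-averaged) over out-of-fold predictions; sensitivity and
  specificity are TP/(TP+FN) and TN/(TN+FP) in percent; AUC uses midrank
  tie handling. Ablations reuse identical fold assignments across feature
  groups, and the single-feature screen reuses identical folds across
  features, so rows are comparable.
* Nomogram: each selected feature's axis maps its observed range to
  nonnegative points, `points_f(x) = 100·(β_f·x − min_range β_f·x)/M` with
  `M = max_f |β_f|·range_f` (that feature spans exactly 0–100 points); the
  total-points → probability map inverts the same affine transformation
  through the logistic function, so the nomogram is an *exact*
  reparameterization of the fitted model (verified to 1e-9). The backing
  fit is the unpenalized maximum-likelihood logistic model; separation is
  detected (diverging coefficients on the standardized scale) and reported
  as an error advising a penalized fallback — the CLI then builds the
  nomogram from the LASSO-refit coefficients. At the default strong-effect
  phantom condition the selected features do quasi-separate a 115-subject
  cohort, so the acceptance run demonstrates the reparameterization
  identity on a simulated logistic dataset in that case.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run at sizes chosen to exercise
the full pipeline faithfully on one CPU: one 52/63 cohort (the study's
class structure) through segmentation, extraction, selection and
evaluation; five null cohorts of 2×20 and ten ablation cohorts of 2×24
using ground-truth masks (the masks are not under test there); twenty
support-recovery simulations at n = 400; fifty random 8×8 images per
brute-force oracle. Larger grids and cohort counts only tighten the same
estimates.

## Known limitations

* Phantom effect sizes are free parameters of the generator, not estimates
  from any patient population; headline percentages on phantoms are
  properties of the chosen condition.
* Texture is 2D-per-slice (averaged), not 3D; the aggregation rule
  (mean vs max-area slice) is configurable but the default is fixed.
* The stability analysis's "segmentation groups" are a perturbation
  emulation, not repeated human raters.
* The single post-contrast phase is emulated; no kinetic features.
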