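# radln

Radiomics prediction of **axillary lymph-node metastasis (ALNM)** from
contrast-enhanced breast-MRI-like volumes.

Whether a breast cancer has spread to the axillary lymph nodes drives
staging, surgery and adjuvant therapy, but the reference procedures
(axillary dissection, sentinel-node biopsy) are invasive. `radln`
implements, as a tested and reusable pipeline, a noninvasive alternative:
predict the nodal status directly from the *primary tumor's* appearance on
dynamic contrast-enhanced MRI, using a radiomic signature.

The pipeline has six stages, one module each:

1. **`radln.phantom`** — a synthetic-cohort generator. Real patient volumes
   for this problem are not publicly deposited, so the package ships a
   lesion-phantom generator that emulates the study structure: two classes
   (default 52 metastasis / 63 non-metastasis), one contrast-enhancing,
   optionally spiculated ellipsoidal mass per subject in noisy background,
   with class-dependent intensity, texture and shape effect sizes.
2. **`radln.imageio`** — NIfTI I/O, `im2double`-style normalization of
   integer data to [0, 1] (division by the dtype maximum), and per-slice
   resampling to a common in-plane grid (384×384 in production).
3. **`radln.segmentation`** — seeded region growing inside a rectangular
   region of interest propagated to all slices: the mask is the connected
   set of voxels within an intensity tolerance *T* of a reference value.
   Quality metrics: Dice overlap against a gold-standard mask and the
   intraclass correlation coefficient ICC(2,1) for per-feature stability
   across repeated/perturbed segmentations.
4. **`radln.features`** — the 58-feature vector per mass:
   16 morphology, 8 gray-level co-occurrence (Haralick), 5 run-length
   (Galloway), 15 gray-gradient co-occurrence, 5 neighboring gray-level
   dependence, 3 Tamura, 6 histogram features. 16 gray levels for the
   co-occurrence matrix, 256 elsewhere; all matrices built strictly from
   in-mask pixels.
5. **`radln.selection`** — LASSO-logistic feature selection: minimize
   (1/n)·binomial deviance + λ‖β‖₁ along a warm-started descending λ grid,
   with λ chosen by stratified 10-fold cross-validation at minimum mean
   held-out deviance.
6. **`radln.modeling` / `radln.nomogram`** — SVM, KNN and LDA under
   stratified 5-fold cross-validation with pooled out-of-fold accuracy /
   sensitivity / specificity / AUC, morphology-vs-texture ablations, a
   per-feature single-factor screen, and a points-based logistic nomogram
   (an exact reparameterization: nomogram probability ≡ model probability).

## Worked example

Everything is reachable from the `radln` command (each subcommand is a thin
wrapper over one library call). A 45-subject phantom cohort, end to end:

```bash
radln simulate --n-met 20 --n-nonmet 25 --seed 17 --out cohort
radln segment  --cohort cohort/cohort.csv --out masks
radln extract  --cohort cohort/cohort.csv --masks masks --out features.csv
radln select   --features features.csv --folds 10 --seed 17 --out selection.json
radln train    --features features.csv --selection selection.json \
               --classifier svm --folds 5 --seed 17 --out report.json
radln nomogram --features features.csv --selection selection.json \
               --out nomogram.json --fig nomogram.png
```

which prints, in order:

```
wrote 45 subjects to cohort
segmented 45 subjects into masks        # QC CSV: mean Dice vs truth 0.9531
wrote 45 x 58 feature table to features.csv
lambda_opt=0.0866933, 9 features selected
{"accuracy": 88.89, "sensitivity": 85.0, "specificity": 92.0, "auc": 0.972, ...}
nomogram with 9 axes written to nomogram.json
```

Reading the numbers: region growing recovers the ground-truth masks with
mean Dice 0.95; the LASSO keeps 9 of 58 features (here a mix of shape —
perimeter, eccentricity, extent — and texture — co-occurrence correlation,
gray-gradient inertia, mean intensity); the SVM on those features reaches
pooled 5-fold accuracy 88.9% and AUC 0.97 on this synthetic cohort. Note
that on small strongly-separated cohorts the unpenalized logistic fit
behind the nomogram can be separated; the CLI then falls back to the
penalized LASSO coefficients (and says so). Scoring patients through the
nomogram:

```bash
radln score --nomogram nomogram.json --patient patients.csv
# S0000  total_points=221.6  probability=0.6943
# S0001  total_points=283.9  probability=0.9225
```

The same flow is available as library calls (`phantom.generate_cohort`,
`segmentation.grow_region`, `features.extract_feature_matrix`,
`selection.choose_lambda_cv`, `modeling.cross_validate`,
`nomogram.build_nomogram`); see the module docstrings.

## Documentation

`docs/methods.md` describes the generative model behind the phantoms, the
exact feature definitions (frozen in `radln.features.FEATURE_REGISTRY`),
the numerical conventions for degenerate inputs, and the known limitations
of desk-scale synthetic evaluation.
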