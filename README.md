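# bmradiomics

Radiomic texture analysis for predicting a binary molecular label (EGFR
mutation status) from contrast-enhanced T1-weighted MRI of brain
metastases — reimplemented as a tested, reusable pipeline and exercised
end-to-end on synthetic lesion cohorts.

The package is aimed at readers who want to study *how* such a radiomics
benchmark behaves — feature definitions, selector/classifier
interactions, optimistic-bias and leakage pitfalls, permutation
calibration — with every stage inspectable and reproducible. No patient
imaging ships with it; a synthetic-cohort generator stands in for the
undeposited data and plants a controllable class-texture effect the
pipeline must recover.

## What it computes

For each lesion (3D volume + binary mask, NIfTI), after bias correction,
cropping and z-score normalisation, a fixed **1209-feature** descriptor:

* 6 first-order histogram statistics (mean, variance, skewness,
  kurtosis, energy, entropy);
* 25 second-order texture statistics: 14 Haralick features of a
  symmetric gray-level co-occurrence matrix (GLCM, 32 levels, 13 unique
  3D offsets) and 11 gray-level run-length (GLRLM) features over the
  same 13 directions;
* 38 × 31 higher-order features: the root-filter-set (RFS) bank — 36
  oriented edge/bar derivative-of-Gaussian kernels (6 orientations × 3
  scales) plus Gaussian and Laplacian-of-Gaussian — applied slice-wise,
  each response map summarised by the same 6 + 25 statistics.

On the lesion × feature table, a benchmark grid crosses **seven feature
rankers** (permutation random-forest importance, ℓ0-norm minimisation,
infinite feature selection, feature selection via concave minimisation,
mRMR, ReliefF, Laplacian score — each behind a Welch t-test prefilter)
with **four classifiers** (random forest, RBF SVM, AdaBoost,
LASSO-logistic) under stratified 10-fold cross-validation (leave-one-out
for the large-lesion subgroup), searching the optimal feature count k by
pooled test-fold AUC (Mann–Whitney, ties ½). Significance of an observed
AUC is assessed by rerunning the whole cross-validated pipeline on
permuted labels: p = (1 + #{permuted AUC ≥ observed}) / (n + 1).

See `docs/methods.md` for the full model description, parameter
defaults, and limitations.

## Worked example

```python
from bmradiomics import (
    CohortConfig, CohortTable, CVPlan, extract_cohort, generate_cohort,
    train_eval_cell,
)

# ~61 patients / ~210 lesions; the mutant class has twice the interior
# texture correlation length (3.0 mm vs 1.5 mm) — the planted effect
records = generate_cohort(CohortConfig(seed=701))
table = CohortTable.from_dataframe(extract_cohort(records))

cell = train_eval_cell(
    table, "rf", "rf", CVPlan("kfold", k=10, seed=17),
    k_grid=[5, 10, 20], seed=11, selector_kwargs={"n_trees": 100},
)
print(f"AUC {cell.auc:.1f} at k={cell.optimal_k}, "
      f"sens {cell.sensitivity:.1f} / spec {cell.specificity:.1f}")
```

This prints (exact values depend on the seed):

```
AUC 94.6 at k=5, sens 95.7 / spec 82.8
```

i.e. with the strong planted effect, random-forest selection +
random-forest classification recovers the class from texture almost
perfectly, pooling held-out predictions over all 10 folds. On an
identical-texture null cohort the same cell scores near AUC 50 and its
permutation p-value lands above 0.05 — the calibration checks in
`tests/test_acceptance.py`.

The numbered drivers under `analysis/` run the full study: cohort
generation, feature extraction, selector benchmarking, the complete
7 × 4 grid with size subgroups (tables and heatmaps under `results/`),
and the permutation tests. On the strong-effect cohort the grid run
prints, for all lesions (selectors as columns, classifiers as rows):

```
            rf    l0  inf_fs   fsv  mrmr  relieff  laplacian
rf        95.1  94.3    60.1  94.3  92.7     94.6       61.9
svm       95.6  94.6    64.7  94.8  94.9     95.7       60.3
adaboost  94.2  96.5    60.9  95.0  95.0     95.2       61.7
lasso_lr  96.3  96.8    77.1  95.8  94.9     96.3       69.5
```

Supervised rankers all land near AUC 95; the two unsupervised ones
(infinite feature selection, Laplacian score) trail badly because the
planted effect is class-conditional texture, not dominant variance.
Small lesions (≤ 10 mm, 10-fold CV) score ~85–90 and large lesions
(> 10 mm, leave-one-out) near 100 — texture statistics are simply better
estimated on more voxels when the effect is uniform across sizes. The `bmradiomics` console script exposes the
same stages as subcommands (`generate`, `preprocess`, `extract`,
`select`, `evaluate`, `run-all`).

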