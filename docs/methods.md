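# Methods

## Problem

The package studies whether quantitative texture descriptors of a
contrast-enhanced 3D lesion image can predict a binary, per-patient
molecular label (mutant vs wild type). The analysis chain is: lesion
volumes + masks → preprocessing → a fixed 1209-entry radiomic feature
vector per lesion → a benchmark grid of 7 feature-selection × 4
classification methods under cross-validation → a label-permutation test
of the best cell's AUC. Because no imaging data are available, the chain
is exercised end-to-end on a synthetic cohort whose class difference is
purely textural.

## Synthetic cohort

`bmradiomics.synthetic` emulates a cohort of 61 patients carrying 1–12
brain metastases each (truncated-geometric count, mean ≈ 3.4; ≈ 210
lesions in total), diameters 3–40 mm drawn from a scaled Beta with mean
10.5 mm (right-skewed, SD ≈ 8 mm), and 29/61 of patients labelled
mutant. The label is assigned per patient and shared by all of that
patient's lesions.

Each lesion is an ellipsoid (longest semi-axis = half the recorded
diameter; minor axes 70–100 % of it) embedded in background noise
(level 10, SD 0.2), multiplied by a smooth multiplicative bias field
(amplitude 0.2, correlation scale 25 mm) emulating coil nonuniformity.
The interior is *set to* a base intensity plus a stationary zero-mean
Gaussian random field — white noise convolved with a Gaussian kernel of
width `correlation_length_mm`, then standardised to exactly the requested
SD. Only second-order structure matters to the texture features, so this
simple family is sufficient. The class effect defaults to a doubling of
the interior correlation length (wild type 1.5 mm, mutant 3.0 mm; field
SD 0.4 for both).

Two generator choices deserve note:

* The lesion interior **replaces** the background rather than adding to
  it. In an earlier design the background white noise leaked inside the
  mask; because a smoother field has less of its variance at the voxel
  scale, the added noise attenuated the smooth class *more*, which could
  even invert the intended ordering of GLCM correlation between classes.
* The optional bright rim shell (ring enhancement) defaults to **off**.
  A rim shared by both classes widens the in-mask intensity range,
  coarsens the effective quantization of the interior field, and in
  cohort-scale experiments erased the class separation of the
  co-occurrence features. It remains available per class via
  `TextureParams.rim_contrast` for experiments where rim contrast *is*
  the effect of interest.

What the generator does **not** model: MRI acquisition physics, partial
volume effects, multi-sequence contrast, anatomical context,
segmentation error, or scanner-to-scanner variation. A pipeline that
recovers the planted texture effect here is shown to be correctly wired
and leakage-free, not to generalise to clinical images.

## Preprocessing

Fixed order: bias correction → crop → normalise.

* **Bias correction** divides by a Gaussian low-pass estimate of the
  multiplicative field (FWHM default 60 mm) and rescales to preserve the
  in-mask mean. This simple surrogate is adequate because the synthetic
  bias is smooth and multiplicative; it is *not* a reimplementation of
  histogram-sharpening (N3-style) correction and will under-correct
  sharper nonuniformity on small fields of view. It can be disabled.
* **Crop** takes the mask bounding box dilated by 2 voxels, clipped to
  the volume.
* **Normalisation** z-scores the whole cropped volume (not mask-only
  statistics), after cropping; both choices are configurable.

## Feature vector (1209 entries)

Registry order: 6 first-order + 25 second-order + 38 × 31 higher-order.

* First-order (in-mask histogram): mean, population variance, moment
  skewness and excess kurtosis (both defined 0 at zero variance),
  histogram energy Σp², entropy −Σp log₂p over 64 equal-width bins.
* Second-order: gray levels quantized to 32 equal-width bins over the
  in-mask range. The GLCM accumulates symmetric co-occurrences over the
  13 unique 3D unit offsets into one matrix (rotation-robust) and is
  summarised by the 14 Haralick statistics (log base 2; 0·log 0 = 0;
  correlation defined 0 at zero marginal SD; the maximal correlation
  coefficient is √(second-largest eigenvalue) of the Q matrix, defined 1
  when only one gray level is active). The GLRLM counts maximal
  equal-level runs along the same 13 directions (runs truncated at the
  mask boundary) and is summarised by the 11 standard run-length
  statistics, with gray-level index counted from 1 and run percentage
  normalised by in-mask voxels × directions.
* Higher-order: the root-filter-set bank — 36 oriented anisotropic
  first/second derivative-of-Gaussian kernels (6 orientations at 30°
  steps × 3 scales (σ_short, σ_long) = (1,3), (2,6), (4,12) voxels ×
  {edge, bar}) plus an isotropic Gaussian and a Laplacian-of-Gaussian
  (σ = 10), 49 × 49 support, derivative/LoG kernels exactly zero-sum,
  all L1-normalised. Filters are 2D by construction and applied
  slice-wise along the axial axis with reflect padding (implemented as
  one shared in-plane FFT per volume). Each response map is z-scored
  within the mask, re-quantized, and summarised by the same 6 + 25
  features.

Degenerate cases are defined, not propagated: a zero-variance response
map contributes the constant-ROI feature values; extraction refuses
masks below 8 voxels and reports the lesion id.

## Selection

A Welch two-sample t-test prefilter (α = 0.05, per training fold) keeps
features with p < α (the single best feature if none survive;
zero-variance features survive only if class means differ exactly).
Seven rankers then order the surviving features, ties broken by
ascending feature index:

* **rf** — permutation importance on out-of-bag samples of a bagged
  forest (default 100 trees, √f features per split): mean OOB accuracy
  drop after permuting one column.
* **mrmr** — greedy max-relevance/min-redundancy with tercile
  discretization and plug-in mutual information (bits), vectorised over
  features.
* **relieff** — k-nearest hits/misses (k = 10, reduced with a warning
  for small classes), Manhattan distance on min-max scaled features.
* **laplacian** — unsupervised locality preservation on a symmetric
  k-NN (k = 5) heat-kernel graph built on standardised samples;
  smaller score is better.
* **inf_fs** — infinite feature selection: adjacency A = ½·max-pairwise
  dispersion + ½·(1 − |corr|); score = row sums of (I − rA)⁻¹ − I with
  r = 0.9/ρ(A) (r halved with a warning if the resolvent is
  ill-conditioned).
* **fsv** — concave minimisation via successive linear programs: hinge
  slacks plus the linearised exponential penalty α·e^(−α·|w|)
  (mixing λ = 0.5), ranked by final |w|, with zeroed features ordered by
  their first-iteration weights. The concavity default is gentle
  (α = 0.5): aggressive concavity collapses the support to one feature
  and leaves the rest of the ranking uninformative, which suits subset
  selection but not a ranker. With exactly duplicated features the LP
  may place all weight on one copy — any split is optimal — so only the
  support, not the symmetric split, is guaranteed.
* **l0** — approximate ℓ0 minimisation by multiplicative reweighting of
  a linear SVM margin (z ← z·|w|, renormalised), eliminating coordinates
  whose scale decays below 10⁻⁶; ranked by elimination round, survivors
  by final weight.

FSV and l0 are iterative *approximations* of concave-minimisation and
ℓ0-norm feature selection; exact solvers are out of scope. No canonical
hyperparameters exist for any of the seven methods in this setting, so
the defaults above are declared design choices.

## Evaluation

Folds are stratified 10-fold (or leave-one-out), deterministic given a
seed. The default grouping is lesion-level, the configuration most
radiomics benchmarks of this kind use — with the acknowledged risk that
lesions of one patient can straddle folds; patient-level grouping (StratifiedGroupKFold, and
patient-wise label permutation) is available and preferable for real
data. For a 210-lesion cohort the 10-fold split is exactly train 189 /
test 21.

Per grid cell and fold: prefilter + ranking on the training lesions
only; for each candidate k the classifier is fit on the top-k features
and scored on the held-out fold. The "optimal feature number" is the k
maximising pooled test-fold AUC — a declared design choice, since no
canonical procedure exists for it — over a default grid k = 2…50.
AUC is the Mann–Whitney pair-counting estimator (ties ½, reported ×100);
sensitivity/specificity/accuracy are computed at the Youden-J optimal
threshold on pooled CV scores (mutant = positive). Classifiers: random
forest (500 trees), RBF SVM with inverse-median-squared-distance
bandwidth and cost 1, AdaBoost with 200 stumps, LASSO-logistic with the
penalty chosen by inner 5-fold CV; features are standardised inside the
SVM/LASSO pipelines. Every fold's train/test lesion ids are logged so
leakage is auditable after the fact.

The permutation test shuffles labels (patient-wise under patient
grouping), reruns the *entire* cross-validated pipeline per shuffle, and
reports p = (1 + #{permuted AUC ≥ observed}) / (n_permutations + 1);
counting ties as exceedances is the conservative reading. Subgroup
analysis partitions at 10 mm diameter (small ≤ 10 mm: 10-fold CV;
large > 10 mm: leave-one-out) and skips a subgroup with fewer than 4
lesions of either class.

## Problem sizes used by the test suite and acceptance script

Cohort-scale checks run at the full cohort size (~61 patients / ~210
lesions) with 32 quantization levels and the full 1209-feature
extraction. The cross-validated cells are scaled for a single CPU:
candidate-k grids of 1–3 values instead of 49, ranking forests of
30–100 trees, classifier forests of 100–500 trees, and 49 permutations
(3 seeds) instead of 500 for the null-calibration check; the
permutation-formula arithmetic is verified at n = 500 directly. Selector
sanity uses 10 planted-feature tables (n = 200, 5 informative of 100,
d = 1.5) per ranker. The permutation super-uniformity property is
checked at nominal level 0.2 over 25 small null cohorts with 19
permutations each.

## Known limitations

* The bias-correction surrogate under-corrects on fields of view much
  smaller than its FWHM; on the synthetic cohort the bias field is mild
  and the downstream z-scoring removes most of its in-mask effect.
* Lesion-level folding leaks patient identity across folds; it is kept
  as the default because it is what comparable benchmarks report, but
  the package exposes, and the methods above recommend, patient
  grouping.
* The optimal-k search maximises pooled CV AUC and reports that same
  AUC, which is optimistically biased for small k grids; an unbiased
  estimate would need nested CV, which is out of scope.
* RFS filters are 2D slice-wise by their standard construction; no 3D
  filter bank, shape/morphology or wavelet features are included.
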