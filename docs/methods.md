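# Methods

This note documents the statistical machinery in `toxsig`, the defaults and
the reasoning behind design choices that the interfaces alone do not convey.

## Data model

All analyses consume a matrix of log2 fold-changes f_gi (gene g, compound
i), each column summarizing one treatment group relative to its matched
vehicle control. When expression-level data with treated/control replicate
samples is supplied instead, `compute_foldchanges` forms
mean(log2 treated) − mean(log2 control) per gene and compound (arithmetic
means on the log scale). Gene and compound identifiers are opaque strings;
probeset-to-gene annotation is out of scope. Compounds carry a class label
in {NGC, NC, GC, UNDEFINED}; every ranking and classification operation
contrasts a designated primary class (default NGC) against a secondary
class (default NC) and requires at least two compounds per class.

Classifier features are z-scores, z = (f − μ)/σ, with μ and the sample SD
(n−1 denominator; the source description does not fix the denominator, and
the sample SD is the conventional choice) estimated on a fitting set of
compounds only — inside cross-validation, always the training fold — and
the stored (μ, σ) re-applied to held-out compounds, so feature scaling
cannot leak test information. Genes with zero SD on the fitting set cannot
be standardized: `zscore_features` raises and names them, while the
resampling pipelines drop them silently (a constant gene in an 18-compound
bag is routine and carries no information). Ranking algorithms instead
assign zero-variance genes the worst ranks, keeping every ranking total.

## Base gene rankers

* **Golub signal-to-noise ratio** r_g = (μ_1g − μ_2g)/(σ_1g + σ_2g) with
  class means and sample SDs of the fold-changes. Informativeness is |r_g|
  (direction-agnostic); the signed value is kept because the weighted
  voting classifier reuses it. If σ_1g + σ_2g = 0 the gene scores 0 when
  the means agree and otherwise one more than the largest finite score (a
  zero-spread perfect separator); such genes are flagged in the result.
* **Statistical tests**: pooled-variance two-sample t-test, Wilcoxon
  rank-sum (exact null distribution for small samples without ties, via
  `scipy.stats.mannwhitneyu`), and a label-permutation test of
  |difference of class means| with add-one smoothing,
  p = (1 + #{perm ≥ obs})/(1 + n_perm), default n_perm = 1000 (a count the
  source leaves open), seeded. Scores are 1 − p; constant genes get p = 1.
* **Linear SVM weights**: |w_g| of a hard two-class SVM (libsvm via
  scikit-learn, linear kernel, C = 1 during ranking, tolerance 1e-6) fitted
  on z-scored fold-changes. Margin methods are scale-sensitive, so
  standardization before fitting is the defensible default; it is recorded
  in provenance.
* **PAM / nearest shrunken centroids**: d_gk = (x̄_gk − x̄_g)/(m_k (s_g + s_0))
  with pooled within-class SD s_g, s_0 = median of the s_g, and
  m_k = sqrt(1/n_k − 1/n). The minus form is the exact standard error
  factor of x̄_k − x̄ under equal variances (some prints of the statistic
  show a plus; the difference is a per-class constant and cannot change
  within-class orderings). Scores are max_k |d_gk| after soft-thresholding
  by Δ; Δ = 0 for ranking since shrinkage only matters for classification.
* **SVM-RFE**: repeatedly fit the linear SVM and eliminate the
  floor(drop_fraction × remaining) genes (≥ 1) with smallest |w|; the
  ranking is the reverse elimination order, with within-batch order by |w|
  descending. drop_fraction defaults to 0.1 (elimination schedule not fixed
  by the source).

Ties everywhere are broken by lexicographic gene ID, making every pipeline
reproducible bit-for-bit under a seed.

## Ensemble feature selection

`run_efs` draws B = 25 subsamples of the training compounds, each holding
90% in-bag. These are subsamples *without* replacement (drawing exactly 90%
distinct compounds), stratified by class so that no bag loses a class —
with 9 + 11 training compounds each bag holds 8 + 10 and leaves one
compound of each class out-of-bag. Per-class in-bag counts are
round-half-up of in_frac × class size, reconciled to the global
round(in_frac × n) by ±1.

Each configured method ranks all genes on every bag (default ensemble:
Golub, SVM, PAM, RFE — the variant with traditional selection methods; the
statistical-test ensemble and combinations are selectable). For the size
grid (11 linearly spaced integer sizes from 2 to 100 by default), a
k-nearest-neighbour classifier (k = 3, a small odd default for ~18 training
compounds; continuous output x/k = fraction of primary-class neighbours) is
trained on the top-s genes of each (method, bag) ranking, z-scored in-bag,
and scored on the out-of-bag compounds; the per-cell ROC score is the AUC
against the out-of-bag labels. Cells whose out-of-bag set degenerates to a
single class are recorded as missing and excluded from aggregation (the
stratified design prevents this, but externally supplied plans may not).

The optimal size k\* maximizes a cubic smoothing spline (smoothing chosen
by generalized cross-validation, `scipy.interpolate.make_smoothing_spline`)
fitted to mean ROC versus size, located from the derivative roots of the
spline together with a unit-step integer grid and clamped to the grid
range. Plateaus and exact ties resolve to the smallest size (parsimony);
with fewer than four defined sizes, or when the spline cannot be fitted,
the argmax of the raw means is used. Note a consequence on strongly
separable data: when every cell reaches ROC 1.0 the curve carries no size
information and parsimony returns the minimum grid size, so the final
signature can be very small even though the consensus ranking below is
well-behaved — size selection is only informative when the out-of-bag
evaluation actually discriminates between sizes.

All M × B rankings are merged by summing each gene's ranks; genes sort
ascending by rank-sum (ties by ID) into the consensus ranking, and the
final signature is its top k\*. Per-method stability is reported as the
mean Kuncheva index over all pairs of per-bag top-k sets for each grid
size.

## Specificity ratio

Direction-agnostic contrasts like |r_g| select any gene that differs
between classes, including genes deregulated only in the *secondary*
class. The specificity ratio replaces the class means by mean absolute
fold-changes m_jg and the SDs by moderated SDs of the absolute
fold-changes:

    s_g = (m_1g − m_2g) / (σ*_1g + σ*_2g).

A gene deregulated only in the secondary class has m_2g > m_1g, hence
s_g < 0, and can never enter the top of the (signed, descending) ranking —
class specificity is structural, not statistical. Shrinkage follows the
shrink-t scheme per class: with v_g the sample variance of the absolute
fold-changes and v₀ their median,

    Var̂(v_g) = n/(n−1)³ · Σ_i (w_ig − w̄_g)²,   w_ig = (x_ig − x̄_g)²,
    λ = min(1, Σ_g Var̂(v_g) / Σ_g (v_g − v₀)²),
    σ*_g = sqrt(λ v₀ + (1−λ) v_g),

so strongly uncertain variance estimates pool toward the median and
λ ∈ [0, 1] always yields a moderated variance between v_g and v₀. With
only n = 2 compounds in a class, Var̂ is undefined and λ is pinned at 1
(full pooling). The two-term denominator σ\*_1 + σ\*_2 with shrinkage
estimated independently per class is the minimal departure from the Golub
form; a pooled-shrinkage variant is available behind a flag. The exact
denominator composition and the printed closed form are not fully fixed by
the source material; this reading is the only self-consistent one
(absolute-fold-change means in the numerator, moderated SDs of the same
quantities in the denominator).

Extraction ranks genes by s_g, preselects the top 100 (configurable), and
keeps genes whose per-gene ROC score q_g = max(AUC_g, 1 − AUC_g) — the
pair-counting AUC of raw fold-changes against the class labels, under the
better of regular/inverted labels, computed via midranks so ties count
one half — reaches the cutoff θ. θ defaults to 0.9, a strong consistency
requirement (with 9 vs 11 compounds it tolerates roughly one discordant
primary compound); the exact cutoff is not recoverable from the source
material and is exposed as configuration.

## Stability

KI(A, B) = (r − k²/n)/(k − k²/n) for equal-sized subsets; +1 for identical
subsets, −1 for disjoint subsets with k = n/2, 0 in expectation for
independent draws. Unequal sizes are rejected rather than truncated, and
k = 0 or k = n is a zero-denominator error. For m > 2 subsets the index is
averaged over all unordered pairs.

## Classification and evaluation

Six classifiers consume z-scored signature features; all outputs are mapped
to [0, 1] with higher = more primary-class-like:

| algorithm | raw output | scaling |
|---|---|---|
| linear SVM | signed decision value d | logistic 1/(1+e^(−slope·d)), slope 1 |
| weighted voting | prediction strength PS ∈ [−1,1] | (PS+1)/2 |
| KNN | x = primary neighbours of k | x/k |
| PAM | class posterior | native |
| Random Forest | class fraction of 500 trees | native |
| Gaussian naive Bayes | class posterior | native |

Weighted voting fits a_g = signed Golub ratio and b_g = midpoint of the
class means per signature gene; a compound's votes v_g = a_g(x_g − b_g)
split into winning and losing sums and PS = (V_win − V_lose)/(V_win +
V_lose), defined as 0 when all votes vanish. The PAM classifier shrinks
centroids by soft-thresholding the d_gk and scores by the Gaussian
discriminant with training-proportion priors. The SVM sigmoid slope is a
free parameter (the source's constant is unrecoverable); the parameter-free
logistic of the decision value is the default.

`nested_cv_evaluate` runs stratified 3-fold outer CV (stratification keeps
both classes in every fold at these sample sizes); within each outer
training fold the signature is re-extracted from scratch (SR or EFS) or a
fixed signature is used, features are z-scored on the fold's training
compounds, and hyperparameters are tuned by an inner stratified 3-fold CV
maximizing mean AUC over small standard grids: SVM C ∈ {0.1, 1, 10, 100},
KNN k ∈ {1, 3, 5}, PAM Δ over 10 quantiles of |d_gk|; Random Forest (500
trees, default feature subsampling), weighted voting and naive Bayes have
no tuned parameters. Per-fold ROC curves are combined by *threshold*
averaging — at every threshold in the merged grid the per-fold FPR and TPR
of the rule "score ≥ t" are averaged — matching how per-fold curves are
aggregated here; vertical averaging is not implemented. The report carries
per-fold AUCs (mean ± SD) alongside the AUC of the averaged curve, and
binary calls per compound at a cutoff maximizing Youden's J = TPR − FPR
(ties resolve to the lower, more sensitive threshold; for separated scores
the midpoint of the gap is returned).

## Pathway enrichment

Upper-tail hypergeometric test per gene set:
p = Σ_{i=m}^{min(n,M)} C(M,i)C(N−M,n−i)/C(N,n), with N the universe size,
M the set size, n the signature genes inside the universe and m the
overlap. The universe defaults to the union of all set members — the
quantity the formula conditions on — with an assayed-genes override;
signature genes outside the universe are dropped from n. p-values are
adjusted across sets by Benjamini–Hochberg (statsmodels) and significance
is called at q < 0.05.

## Synthetic data

The generator emulates the shape of a short-term rat-liver study: 9
primary-class and 11 secondary-class compounds (mirroring a 9 NGC / 11 NC
panel), 5000 genes by default, and planted populations — 50
primary-specific genes (one sign and magnitude |μ| ~ U(1, 2) log2 units
drawn per gene, plus N(0, 0.3) per-compound noise in the primary class and
N(0, 0.3) background in the secondary class), 10 secondary-specific
confounders (mirrored; kept deliberately fewer than the primary set, as
consistent responses across a pharmacologically diverse non-carcinogen
panel are rarer than a class-wide carcinogen response), 25 shared
responders (deregulated equally in both classes), 25 inconsistent decoys
(strong effect in the primary class with a guaranteed-mixed random sign
per compound — sign patterns that come out nearly constant are redrawn so
the planted role is true by construction), and i.i.d. background noise
elsewhere. An expression-level mode generates 3 treated + 3 control
replicate samples per compound around per-gene baselines to exercise the
design-to-fold-change path.

What this emulates: the sample-size regime, class imbalance, the
specific/confounded/shared/inconsistent gene taxonomy that the two
extraction methods are designed to tell apart, and effect sizes typical of
strong hepatic responses. What it does not: probe-level artifacts, batch
effects, correlated gene modules, dose–response structure, or compound
heterogeneity within a class (every primary compound responds to every
planted gene). Because planted effects of 1–2 log2 units against 0.3 SD
noise are strongly separable, classifier AUCs saturate near 1 and the EFS
size-selection curve is flat at its ceiling; passing tests on this
generator therefore demonstrate correctness of the machinery and the
specificity/consistency contrasts, not realistic absolute performance
levels.

## Problem sizes and determinism

Default analyses (5000 genes, 20 compounds, 25 bootstraps × 4 methods,
11 grid sizes) run in well under a minute on a single CPU; the test suite
uses 300–1200-gene datasets for unit-level checks and the full default
dataset for end-to-end checks. Every stochastic step (subsampling,
permutation tests, CV splitting, Random Forest) derives its stream from an
explicit seed, and tie-breaks are deterministic, so all artifacts —
signatures, reports, simulated datasets — reproduce byte-identically under
a fixed seed.

## Known limitations

* Two-class contrasts only; no multiclass GC/NGC/NC discrimination.
* The SR denominator composition and ROC cutoff encode one documented
  reading of an underspecified description (see above).
* Threshold-averaged ROC is the only curve-averaging mode.
* EFS size selection is uninformative on data where out-of-bag
  classification saturates (flat curve ⇒ smallest grid size by parsimony).
* No batch-effect handling; inputs are assumed normalized upstream.
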