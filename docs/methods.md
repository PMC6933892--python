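# Methods

This note documents the models, conventions, and numerical choices behind
`clinomics`, and what the synthetic-data generator does and does not emulate.

## Data model and import conventions

An *omic* is a feature × sample numeric matrix; missing entries are NaN and
every reader treats the tokens `""`, `NA`, `NaN`, `null` (case-insensitive)
as missing. Duplicate feature or sample identifiers are hard errors in every
reader — silent deduplication is a classic source of irreproducible results.
When a matrix and a phenotype table disagree on the sample set, the
intersection is taken with a warning and the matrix's column order is
canonical; rows are never silently reordered.

Clinical labels are typed `categorical`, `ordinal`, `numeric`, or `survival`
(a time ≥ 0 / event ∈ {0,1} pair). Auto-typing of undeclared columns:
all-numeric columns become numeric unless they are 0/1 flags; column pairs
`<base>_time` / `<base>_event` assemble into a survival label; everything
else is categorical (with a warning above 10 distinct values). Ordinal
typing is never inferred — a declared level order is required, because no
safe inference exists for strings like tumor stages with cohort-specific
coding.

Multi-omic collections are stored as an open, diffable layout: a
`manifest.json` naming each omic's TSV, the clinical TSV, and the label-type
declarations. A write/read round trip preserves identifiers, label types and
values (to float-formatting precision, < 1e-9 here).

GEO support covers the series-matrix dialect only (table between the
begin/end markers, `!Sample_characteristics_ch1` lines of `key: value`
form), which is what the series files distributed for expression datasets
contain; full SOFT parsing is out of scope.

## Preprocessing

Variances and z-scores use ddof=1 throughout, computed over non-missing
entries. `row_normalize` maps constant rows to all-zero with a warning
rather than erroring, since variance-filtered matrices routinely contain a
few constant rows. Filters are pure subset operations — surviving values are
bitwise-identical to their originals — and all sorting is stable, so ties
never reshuffle. PCA imputes missing values to the feature mean before
centering; this is deterministic and adequate for exploration, and the
docstring says so rather than pretending to be an imputation method.

## Clustering

K-means is Lloyd's algorithm with k-means++ initialization, 10 restarts by
default, and per-restart seeds spawned from one user seed (bit-identical
reruns). The *correlation* distance standardizes each item vector to zero
mean and unit norm, under which squared euclidean distance equals
2(1 − Pearson r); both metrics therefore share one code path and one
objective (within-cluster sum of squared distances), which is reported and
non-increasing across iterations. A cluster emptied during iteration is
re-seeded from the point farthest from its centroid. Hierarchical clustering
delegates to scipy's agglomerative linkage (average/complete/ward; ward
requires euclidean) and keeps the leaf order for heat-map-style reordering.

A caveat measured during development: greedy complete-linkage agglomeration
is *not* guaranteed to minimize the maximum intra-cluster distance; on
unstructured Gaussian point sets of size ≤ 8 it misses the brute-force
optimum in roughly a third of instances. On clearly separated planted
blocks it is reliably optimal, which is the regime the oracle tests cover.

## Enrichment

Tests are chosen per label type: hypergeometric upper tails for categorical
labels (per cluster × category cell, with a min-cell × Bonferroni-by-
category-count label-level summary — conservative and transparent, with all
raw cell p-values emitted); Kruskal–Wallis plus one-vs-rest rank-sum for
numeric labels; the same on declared level ranks for ordinal labels; k-group
and one-vs-rest log-rank for survival labels. The one-vs-rest rank-sum uses
the exact null distribution when both groups have ≤ 25 tie-free
observations, midranks with the normal approximation otherwise.

BH correction is stratified: one pass per label type over label-level
p-values, so adding labels of another type never changes existing q-values.
Gene-set enrichment intersects each set with the declared background, BH-
corrects across sets within each feature cluster, and reports the top 5 per
cluster by (q, p).

## Survival

The Kaplan–Meier estimator uses the convention that censorings at an event
time count as at risk for the events at that time. The log-rank statistic is
the Mantel–Haenszel chi-square with the hypergeometric variance (df = k−1;
one-vs-rest collapses the complement, df = 1). Cox fits are univariate,
maximizing the Efron-tied partial likelihood by Newton–Raphson with
convergence |Δβ| < 1e-8 within 50 iterations; the covariate is standardized
internally for numerical stability and β mapped back. Efron rather than
Breslow because ties are the norm in day-resolution follow-up. Degenerate
covariates (zero variance) return β = 0, HR = 1, p = 1 with a flag; monotone
likelihoods (perfect separation) are flagged non-converged with the drift
sign. Expression-derived labels use a median split by default, with samples
exactly at the median assigned to "Low" (deterministic); a quantile mode
marks the middle of the distribution missing instead.

Time units are whatever the survival label carries; nothing converts
days/months.

## Biomarkers

The default two-group test is Welch's t (unequal variances are the rule in
expression data); pooled-variance t is a flag. log2 fold change is the
difference of group means when the matrix's `value_scale` declares a log
scale, log2 of the mean ratio for positive linear-scale data, and the plain
mean difference otherwise — the choice is recorded in the table's metadata
to avoid silent scale bugs. BH is the only multiple-testing procedure
offered. Correlation ranking uses pairwise-complete samples and requires at
least 3 shared observations per pair.

## Classifier

CART with Gini impurity; candidate thresholds are midpoints between
consecutive distinct sorted values; ties in impurity break toward the lower
feature index, then the smaller threshold, making fits bit-reproducible.
`max_depth = 0` yields the majority-class leaf. Missing values at prediction
time follow the majority direction of the training samples routed through
the node. Cross-validation is stratified by default (subtype labels are
typically imbalanced) with a warned fall-back to unstratified folds when a
class is rarer than the fold count. "Loss" always means the
misclassification fraction. Parameter optimization is a grid search over
(max_depth, min_leaf) minimizing mean CV loss, with ties broken toward
smaller depth, then larger min_leaf — a simplicity preference standing in
for pruning. The random-tree ranking trains each tree on a bootstrap sample
and a random feature subset and counts, per feature, the number of trees
using it in at least one internal node.

## Multi-omic integration

Per-omic sample distances are euclidean on row-normalized features. The
affinity kernel is a Gaussian density with a locally adaptive bandwidth:
ε_ij = (mean distance of i to its K nearest neighbours + the same for j +
d_ij)/3 and W_ij = exp(−d²_ij / (2 (μ ε_ij)²)). Note the bandwidth enters
squared: the variant with μ·ε unsquared in the denominator (as sometimes
printed) is dimensionally inconsistent and in practice collapses the
affinities to a near-binary K-NN graph, which destroys the diffusion's
integration gain — this was measured, not assumed.

SNF builds, per omic, a row-stochastic full kernel P (self-weight ½) and a
row-stochastic K-NN-restricted kernel S, then iterates
P(v) ← S(v) · avg_{u≠v} P(u) · S(v)ᵀ with re-symmetrization and an identity
regularization per round (without which T = 20 rounds converge to a uniform
matrix); the fused network is the row-normalized symmetrized average of the
final P(v). The NEMO-style route normalizes each affinity row by its K-NN
affinity mass, keeps only K-NN entries, symmetrizes, and averages across
omics; k can be chosen automatically by the largest normalized-Laplacian
eigengap among 2..10. Both are cut by spectral clustering (k smallest
eigenvectors of the normalized Laplacian, row-normalized, k-means).
Defaults: K = 20 (or ⌈n/10⌉ if smaller), μ = 0.5, T = 20.

Consensus clustering subsamples 80% of samples without replacement 100
times, runs k-means on the concatenation of the row-normalized omics (the
"multi-omic modification"; a per-omic co-association alternative was
considered and not made default), and records co-clustering frequencies
among co-sampled pairs. PAC — the fraction of off-diagonal consensus entries
in (0.1, 0.9) — selects k; the final partition is an average-linkage cut of
1 − consensus. The same subsample sequence is shared across candidate k for
comparability.

Inter-omic correlation pairs features by shared identifier (expression vs
methylation of the same gene) or scans all cross-pairs keeping the top N by
|r|; the default sort puts the strongest anti-correlations first, since
methylation–expression repression is the motivating pattern.

## Synthetic cohorts

The generator plants k subtypes (default 4, 300 samples — a desk-scale
stand-in for a breast-cancer-sized cohort) and emulates:

* expression: unit-variance Gaussian noise, each subtype shifting its own
  random 10% feature subset by `effect_size` SD (default 2.0 — a moderate,
  recoverable but not trivial signal);
* methylation: a logistic squash of a latent equal to ± the expression of
  the same gene plus N(0, 0.3²) noise, giving (0,1)-bounded beta-like values
  and a planted anti-correlated subset (20% of methylation features,
  Spearman r ≤ −0.8 at n ≥ 100);
* copy number: a diploid baseline with subtype-specific ±1 integer shifts on
  10% of features plus N(0, 0.3²) noise;
* survival: exponential event times with baseline rate 1e-3 (mean 1000 time
  units) scaled by per-subtype hazard ratios (default geometrically spaced
  1..3), with exponential censoring calibrated so the expected censored
  fraction equals `censor_rate` (default 0.3);
* labels: the subtype label flipped to a random other subtype with
  probability `label_noise` (default 0.1), plus an independent nuisance
  site label and a numeric age label.

It does **not** emulate count-distributed RNA-seq noise, batch effects,
segment-structured copy number, missing-at-random patterns, or informative
censoring — a green test on this world establishes implementation
correctness and statistical calibration, not robustness to those artifacts.
Identical parameters and seed give bit-identical collections.

## Calibration worlds used by the acceptance tests

The simulation-based acceptance checks state their worlds explicitly: the
log-rank type-I error and enrichment-uniformity checks use exact null
worlds; Cox recovery uses β = ln 2 at n = 500 with 30% censoring; the
clustering world shifts 10% of 20 features by 6 SD (the package-wide
convention that effect sizes are per-feature shifts in SD units); the
integration-gain world uses three independent omics with 0.8-SD shifts,
chosen so that every single-omic clustering stays below ARI 0.7, the
condition the gain claim is about.

## Known limitations

* Cox fitting is univariate only; no covariate adjustment, diagnostics, or
  competing risks.
* NEMO-style clustering requires the intersected sample set; partial-data
  mode (samples missing whole omics) is not implemented.
* Gene sets are flat GMT collections; no ontology-graph propagation.
* The CLI holds matrices in memory; it targets desk-scale cohorts
  (thousands of samples), not out-of-core datasets.
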