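# Methods

`geneximb` classifies cancer types from gene-expression microarray intensities
under two pathologies that dominate this data: class imbalance (per-class
sample counts as skewed as 52:9) and the curse of dimensionality (thousands of
genes, tens of samples). The pipeline is

    normalize → oversample (training data only) → select genes → classify → evaluate

with every fitted statistic — normalization extrema, synthetic samples, gene
rankings — computed strictly on training data.

## Normalization

Each gene is min–max rescaled, `x' = (x − x_min)/(x_max − x_min)`, to [0, 1] on
its fitting set. Whether the extrema should be fitted before or after the
train/test split is genuinely open; the default is train-only (no test
leakage), with `normalize_scope="full"` available for the whole-dataset
interpretation. Constant genes (`x_max == x_min`) map to 0, which keeps them
inert — they carry no discriminative signal, and any other constant would be
arbitrary. Out-of-range test values extrapolate linearly and are not clipped:
clipping would silently discard the information that a test sample lies
outside the training range.

## Oversampling

All resamplers are implemented from first principles; only the neighbor
searches, SVM fit and k-means clustering call scikit-learn/scipy primitives.

The **balance-to-majority plan** raises every class's training count to the
majority class's count. **SMOTE** cycles through the minority samples in index
order; each needed synthetic sample interpolates between the current seed and
a uniformly drawn one of its k nearest same-class neighbors (Euclidean, k = 5
by default — the canonical choice; no value is prescribed by the procedure
itself) with gap ~ U(0, 1). **Borderline-SMOTE** restricts seeds to the
"danger" set: minority samples whose m = 10 nearest whole-set neighbors are at
least half majority-class (noise when all m are, safe when fewer than m/2).
B1 interpolates toward minority neighbors; B2 flips a fair coin per sample and
otherwise interpolates toward one of the k nearest majority neighbors with
gap ~ U(0, 0.5), keeping the synthetic point on the minority side.
**SVM-SMOTE** seeds from the minority support vectors of a linear soft-margin
SVM (C = 1; linear is well-behaved at p ≫ n and keeps support vectors
interpretable); seeds in majority-dominated neighborhoods interpolate inward,
the rest extrapolate outward, `new = seed + g·(seed − neighbor)`.
**KMeans-SMOTE** clusters the whole training set (k-means,
`n_clusters = min(8, n/2)`), keeps clusters whose minority fraction is ≥ 0.5
with at least two minority members, apportions the synthetic budget across
them proportionally to mean pairwise minority distance raised to
`min(2, sqrt(p))` (sparser clusters receive more), rounds by largest
remainder so totals are exact, and runs SMOTE within each cluster.

Multiclass data are handled one-vs-rest: each non-majority class is
oversampled with all other classes pooled as "majority" for the neighborhood
rules, which is the only reading consistent with a balance-to-majority target
across 5–7 classes.

Every synthetic sample records `(seed_index, neighbor_index, gap)` and
satisfies `values == seed + gap·(neighbor − seed)` exactly, so resampling is
fully replayable and auditable. The SVM-SMOTE extrapolation step stores a
negative gap (`gap = −g ∈ [−1, 0)`); interpolated gaps lie in [0, 1]. Gap and
neighbor draws come from a dedicated `numpy` generator stream per call, so the
choice of variant never perturbs other stages' randomness. A minority class of
size 1 raises by default (`allow_duplicate_fallback=True` duplicates instead);
k is clamped to class size − 1 with a warning. Empty danger sets, absent
minority support vectors and empty eligible-cluster sets all fall back to
plain-SMOTE seeding with a warning rather than failing mid-pipeline.

## Gene selection

Expression is discretized per gene before scoring. The default discretizer is
recursive entropy partitioning with MDL stopping (the Fayyad–Irani rule): a
binary cut is accepted only when its information gain exceeds
`(log2(N−1) + log2(3^c − 2) − c·H(S) + c1·H(S1) + c2·H(S2))/N`. On pure-noise
genes this almost never accepts a cut, so noise genes collapse to a single bin
and score exactly zero under both statistics — the discretizer doubles as the
"threshold of zero" filter. An equal-width alternative (10 bins) is available.

Chi-square scores each gene by `Σ (O − E)²/E` over the bin × class contingency
table; information gain by `H(class) − H(class | bin)` in bits. Both are
nonnegative, so the zero-threshold filter keeps strictly positive scores
(a "negative ranking" cannot occur for either statistic). Ties are broken by
gene id for a deterministic order. `select_top_n` takes the first N positive
survivors; **ChiSIG** intersects the chi-square and information-gain
selections, ordered by chi-square rank (some order must be chosen; chi-square
is the first-named method), and satisfies
`|ChiSIG| ≤ min(|ChiS|, |IG|)` by construction.

When oversampling is enabled the default stage order is oversample-then-select
(selection sees the balanced training set); `select_before_oversample=True`
provides the other order. The two orders select different gene sets on
imbalanced data, which is itself a tested property.

## Classification

The package's own classifier is a homogeneous ensemble of 1-NN, 3-NN and 5-NN
models sharing one training matrix and Euclidean metric. Each base model votes
the plurality class of its k nearest neighbors (distance ties broken by
training index via stable sort; vote ties by the nearest neighbor's class);
the ensemble takes the majority of the three base predictions, ties going to
the smallest-k model — the most local opinion, and a rule is required for
multiclass ties. On training sets smaller than 5 the infeasible k values are
dropped with a warning.

The MLP hidden-layer sizing rule is the rounded (half-up) average of input and
output dimensions — 300 genes and 7 classes give 154 neurons — implemented as
`(a + b + 1) // 2`. Other backends (random forests with 100 gini trees,
bagging with 10 estimators, SVM/decision-tree/logistic stacking and voting,
gradient boosting, XGBoost, SMO-style SVC with poly kernel and C = 1,
one-vs-one multiclass) are scikit-learn / xgboost estimators behind a validated
configuration layer; their internals are deliberately not reimplemented. The
PUK kernel has no scikit-learn counterpart and ships as an RBF preset named
`smo_svm_puk_approx`, a documented approximation.

## Evaluation

Confusion matrices are exact cross-tabulations; per-class precision, recall
and F1 come from one-vs-rest TP/FP/FN/TN in percent; a zero denominator scores
0 with a warning. Headline averages are **support-weighted**, under which
weighted recall equals accuracy identically
(`Σ (n_c/N)(TP_c/n_c) = Σ TP_c/N`) — an invariant asserted on every report.
Cross-validation is stratified, shuffled under a fixed seed, and refits the
entire pipeline inside each training fold; the fold count drops to the
smallest class count (with a warning) when that count is below the requested
folds. The pooled (micro) confusion matrix across folds is the headline CV
number, with per-fold metrics attached. Each fold asserts that no synthetic
sample's provenance references a test-fold sample. Baseline comparison labels
an accuracy delta positive/negative beyond ±0.5 percentage points and
negligible inside it (an artifact convention). A PCA front end (50 components
by default, fitted on training data only) serves the high-dimensional
benchmark grid.

## Synthetic data

The generator emulates the benchmarks' structure: class c's informative genes
are `Normal(base + c·effect·sd, sd)`, noise genes `Normal(base, sd)`, clamped
at zero, with `base = 8`, `sd = 1` (a log2-microarray-like intensity scale)
and informative columns at seeded random positions. It reproduces the shapes
of four public panels — a 5-class leukemia microarray set (64 samples, minority
8), a 7-class leukemia-subtype set (327), binary ALL/AML (72) and colon
tumor/normal (62) — with their published holdout splits, at 500 genes by
default (full-scale gene counts are available through the spec but add
nothing to the properties under test). What this generator does **not**
emulate: probe-level artifacts, batch effects, heavy-tailed intensity
distributions (beyond the optional log-normal flag), and gene–gene
correlation. Passing tests therefore demonstrate algorithmic correctness and
leakage-safety, not clinical performance on real microarrays.

Null-data sanity uses a one-sided binomial test: after balance-to-majority
oversampling a signal-free classifier's expected accuracy is about
1/n_classes, *below* the majority-class rate, so the meaningful check is that
accuracy is not significantly **above** that rate (α = 0.01, pooled over 20
seeds), not two-sided equality with it.

## Determinism

A single root seed derives every stage stream (fold shuffling, gap draws,
backend seeds) through SHA-256-keyed `SeedSequence`-style derivation, all
below 2³¹. Identical configuration and seed reproduce byte-identical report
JSON.

## Known limitations

- The recursive MDL discretizer is O(n log n) per gene but pure Python per
  node; at 22k genes it takes tens of seconds, acceptable for the intended
  sample sizes (≤ a few hundred).
- `smo_svm_puk_approx` is an RBF stand-in for the Pearson-universal kernel.
- ARFF support covers the WEKA numeric-attributes + nominal-class dialect
  only (sparse ARFF and string attributes are out of scope).
- Headline accuracies reported for the real public benchmarks are not
  reproduced here: those require downloading the original datasets, which is
  outside this package's scope; the synthetic fixtures match their shapes
  only.
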