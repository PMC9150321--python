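# Methods

This note documents the models and procedures implemented in `oncosift`,
the parameter defaults and why they were chosen, the numerical conventions
that make runs reproducible, and the limits of what the synthetic-cohort
tests demonstrate.

## Input model

The pipeline consumes annotated cell × gene matrices (AnnData/h5ad) whose
values are counts normalized to the total reads per cell and transformed as
log2(x + 1). Two assumptions are load-bearing and are checked by
`validate_normalization`:

* the matrix is **not** z-scaled — scaling destroys the nonnegativity and
  the rank structure the scorer depends on;
* the matrix carries the **complete** profiled gene set, not a
  highly-variable-gene subset — pre-filtering silently changes every
  recovery-curve denominator and the 80% coverage guard.

Raw counts (layer `"counts"`) are needed only for CNV inference. Gene
identifiers are matched as exact symbols after whitespace stripping; no
alias resolution is attempted, for determinism.

## Differential expression: the inflated-variance t-test

For each gene, classes *up* (n₁ cells) and *down* (n₀ cells):

t = (x̄₁ − x̄₀) / √(s₁²/n₁ + s₀²/n₁),   dof by Welch–Satterthwaite on the
same two terms.

Both variance terms are divided by n₁, the size of the class under test.
Compared with Welch's test this inflates the standard error whenever
n₁ < n₀ — the usual situation for a minority tumor class — making the test
deliberately conservative. The implementation is cross-checked in the test
suite against both a scalar re-derivation of the formula and scanpy's
independent `t-test_overestim_var` route. Zero-variance genes with equal
means give t = 0, p = 1; with unequal means, |t| = ∞, p = 0. P-values are
two-sided and BH-FDR-adjusted within each (dataset, comparison).

The log2 fold change is the difference of class means on the log2 layer —
an approximation that avoids exponentiating already-transformed data.

## Consolidation

Per comparison, a gene's cross-dataset average log2fc uses **only the
datasets where it passed p_adj < 0.1**; genes passing nowhere are dropped.
The denominator choice (count of passing datasets, not all datasets) avoids
penalizing genes missing or underpowered on one platform; genes absent from
a dataset are treated as failing there. Ranking ties are broken
lexicographically. Top-300 lists are intersected across comparisons for the
up-signature (a tumor marker must beat *every* contrast) and unioned for
the depleted signature (a gene missing from any normal context is
informative). An empty intersection returns `None` with a warning rather
than an unusable empty signature.

## Recovery-curve scoring

Within each cell, genes are ranked by descending expression with
lexicographic tie-breaking (the upstream AUCell tool breaks ties randomly;
determinism was preferred — scores differ from AUCell's only on exact
expression ties). The score integrates the recovery step function to depth
`max_rank = ⌈0.05 · n_genes⌉` (the conventional top-5% depth; the depth is
exposed in `ScoringConfig`) and divides by the best achievable area for the
number of signature genes present, so scores live in [0, 1] with 1 meaning
"all present signature genes occupy the top ranks".

Signature genes absent from the dataset are dropped *after* the coverage
guard passes; below 80% coverage the operation refuses with the measured
fraction. The scorer targets single-cell matrices; rank-based scores are
known to misbehave on some bulk profiles, which are out of scope.

## Score classifier

A two-feature logistic regression (scikit-learn, lbfgs) with a weak L2
penalty (inverse strength C = 1.0) maps (tumor_score, normal_score) to
P(tumor). No hyperparameter search is performed. Class order is fixed as
(normal, tumor) everywhere. Datasets are scored independently and the score
tables concatenated for training — scores are within-cell ranks, so no
cross-dataset normalization is applied.

An operating-regime caveat discovered during development and reflected in
the tests: because the scores have magnitude ~0.1, the fixed weak penalty
needs a few thousand training cells before the likelihood dominates; with
only hundreds of cells the classifier degenerates to the majority class.
The synthetic defaults (2000 cells/dataset, two training datasets) sit in
the regime the method is intended for, where annotated cohorts provide
thousands of cells.

## Network propagation

The cell–cell graph restricts the matrix to the union of signature genes,
reduces it by PCA (50 components, capped at the feature count), finds k = 30
Euclidean nearest neighbors and symmetrizes them into fuzzy-union
connectivity weights in [0, 1] with zero diagonal — the standard
single-cell neighbor graph, built on the signature feature space only.

Propagation is an iterative masked diffusion:

1. stringency thresholds at iteration t: N(t) = N0·e^(−λt) on the tumor
   side, with N0 the 0.9 quantile (linear interpolation between order
   statistics) of the per-cell (tumor − normal) score difference, and a
   mirrored threshold decaying identically from the 0.9 quantile of
   (normal − tumor);
2. cells clearing neither threshold have both class probabilities masked
   to zero;
3. propagated = connectivities · masked probabilities, renormalized per
   cell; cells whose propagated row is all zero (no unmasked neighbor)
   keep their previous probabilities and label;
4. labels = argmax; stop when < 0.1% of labels change, or at `max_iter`
   (50) with a warning.

Design choices made where the procedure was genuinely open:

* **Two-sided seeding.** A single threshold derived from the signed score
  difference and applied to its absolute value leaves no confident-normal
  seeds whenever normal cells sit nearer zero on the difference scale than
  the tumor-side 90th percentile — propagation then fixes almost no
  mislabeled normal cells. The per-side quantiles make both classes
  contribute seeds symmetrically; with both in place, 10% planted label
  flips are fully corrected on synthetic cohorts without corrupting
  correct labels.
* **Fixed N0.** The initial quantile is computed once and decayed, rather
  than re-quantiled each iteration — matching the decay law as stated and
  guaranteeing that the seed set only grows.
* λ defaults to 0.25 per iteration (no published value; chosen so the
  threshold halves roughly every three iterations, letting consensus form
  before low-confidence cells join).

## CNV profiles and proofreading

The profile is the smoothed relative-expression core of expression-based
CNV inference; hidden-Markov state calling and tumor subclustering are
deliberately not implemented, because the proofreading model consumes the
continuous profile directly. Pipeline, in order: keep positioned genes with
mean raw count ≥ 0.1 → normalize counts to the median library size and
log2(x + 1) (the normalization inside this stage is the package's choice;
only relative level differences survive the next step) → subtract the
per-gene mean of the reference (normal) cells → clip to ±3 → centered
moving average of 101 genes per chromosome (truncated windows at
chromosome edges, never crossing a boundary) → subtract each cell's
median. Reference cells are the pipeline's own normal calls in
self-supervised mode, or expert labels in harness mode.

Proofreading trains a logistic regression (C = 1.0) on the profiles with
the pipeline's labels as pseudo-targets, predicts the same cells (the model
is assumed not to overfit this low-capacity task), and flips a label iff
the opposite class receives probability > 0.9. The 0.9 cutoff
operationalizes "highly probable" (no published number) and is exposed in
`ProofreadConfig`; flips are therefore conservative — concordant labels are
never touched and flips are bounded by the number of discordant cells. The
per-cell mean and variance of the profile are exported as the diagnostic
that separates misclassified tumor cells from true normals.

`train_cnv_baseline` reproduces the generalization experiment's structure:
per-cohort random forests on (profile → expert label), evaluated on every
cohort. On synthetic cohorts with disjoint planted gain segments the
off-diagonal balanced accuracy collapses toward 0.5 while diagonals stay
near 1 — copy-number patterns are cohort-specific, which is precisely why
CNVs serve as a proofreading signal rather than a universal classifier.

## Synthetic cohorts

The generator emulates the statistics the method relies on: negative-
binomial counts (overdispersion α = 0.5, var = μ + αμ²) with log-normal
library sizes (σ = 0.3); gene-wise log-normal base means; per-dataset
multiplicative batch offsets (log2 sd 0.3) that confound naive expression
comparison but not within-cell ranks; a 1/8 tumor fraction (≈7:1
normal:tumor imbalance, typical of annotated tumor datasets); planted
tumor-up and tumor-depleted marker sets (150 genes each, mean log2 shift
1.5) shared across a cohort's datasets and placed outside CNV segments so
marker and copy-number signal stay orthogonal; and contiguous CNV segments
(default: one 300-gene 2× gain) multiplying tumor-cell count means. The
default size (4 datasets × 2000 cells × 6000 genes) keeps a full pipeline
run within minutes on one CPU while sitting inside the classifier's
operating regime.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: cell-type substructure within the normal
compartment, dropout beyond NB sampling, doublets, ambient RNA,
platform-specific gene detection, partial or hierarchical annotations, and
tumor subclones with distinct CNV architectures. Results on these cohorts
demonstrate correctness of the machinery under the model's assumptions,
not clinical performance.

## Numerical conventions

* All tie-breaks (expression ranks, fold-change ranks) are lexicographic by
  gene symbol; all quantiles use linear interpolation between order
  statistics — both documented for bit-reproducibility.
* Every source of randomness flows from one seed; pipeline stages derive
  stable child seeds (`sha256(seed:stage)` truncated below 2³¹) so stages
  can be re-run in isolation.
* Genomic coordinates in the position table are 1-based inclusive; only
  the (chromosome, start) ordering is consumed.
* Degenerate inputs have defined behavior: single-class pseudo-labels skip
  proofreading with a warning; all-zero propagated rows keep their previous
  label; empty intersections warn and return `None`; coverage below 80%
  and k ≥ n_cells raise typed errors.

## Known limitations

* Symbol-level gene matching only; cross-platform harmonization is the
  caller's responsibility.
* The depleted ("normal") list is filled to the top-300 quota even when
  fewer genuinely depleted genes exist, admitting weakly informative genes.
* Proofreading is applied once, not iterated with re-propagation.
* Bulk expression scoring and HMM-based CNV state calling are out of scope.
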