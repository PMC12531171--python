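# Methods

This note documents the models and numerical choices behind `glycosig`,
what the synthetic-data generators do and do not emulate, and the design
decisions taken where the procedure was genuinely open.

## Single-sample enrichment scoring

The per-cell/per-sample gene-set score is the ssGSEA rank statistic.
Within each observation, genes are ranked by expression with average
ranks on ties; the score is the sum of the running sum of a random walk
over the ranking from highest to lowest expression, with in-set
increments `rank^α` normalized to total 1 (default `α = 0.25`) and
out-of-set increments `1/(G − |S|)`. Scores are then min–max rescaled
across the matrix's observations to span `[-1, 1]`, so scores are
comparable only within a single scored matrix and cross-matrix scores
are never mixed. Being rank-based, the statistic is invariant to any
strictly monotone per-observation transform of expression, and
duplicated genes in a set are deduplicated before scoring. Kernel-CDF
variants of gene-set variation analysis exist; this package deliberately
implements the ssGSEA statistic, which is fully specified from first
principles, and states its guarantees as properties (monotone
invariance, planted-signal recovery) rather than equality with any
particular external implementation. A `zmean` alternative (mean of
gene-wise z-scores over the set) is available for bulk matrices;
zero-variance genes are skipped with a warning.

Cell QC uses strict inequalities throughout: a cell is removed when
detected genes `> 7,500` or `< 200`, total reads `> 75,000`, or the
mitochondrial read fraction `> 0.20` — a cell at exactly 0.20 is
retained. LogNormalize maps counts to `ln(1 + 10⁴·c/total)` per cell.

## Signature derivation

Per dataset: Gx = genes with Spearman `R > 0` and BH `FDR < 1e-5`
against the glycolysis score among malignant cells (strict
inequalities; FDR within each dataset, never pooled across datasets —
the correlation filter is a per-dataset decision). The criteria for
"significantly overexpressed in malignant cells" (Gy) were an open
choice; the conventional single-cell marker defaults were adopted:
two-sided rank-sum test, BH `FDR < 0.05`, log-scale mean difference
`> 0.25`, all three config-exposed. Gn = Gx ∩ Gy, so every Gn gene has
a positive recorded correlation.

Aggregation takes, for each gene in the union of Gn sets, the geometric
mean of its Spearman R values from exactly the datasets whose Gn
contains it (all positive by construction); negative correlations the
gene may show in other datasets are ignored. Membership requires
`R̄ > 0.3` strictly — implemented with a `1e-12` guard so a geometric
mean equal to the threshold up to floating-point rounding is excluded —
and support in at least `min_datasets` datasets (default 1, i.e. no
support floor, configurable). The output is invariant to dataset input
order (genes and datasets are processed in sorted order).

Spearman p-values use the t approximation with `n − 2` degrees of
freedom for `n > 10` and exact permutation enumeration otherwise;
rank-sum and Mann–Whitney p-values use exact enumeration of group
assignments when both groups have ≤ 8 observations and the
tie-corrected normal approximation (no continuity correction) above
that. Constant genes get `R = NaN` and are excluded from the FDR
adjustment.

## Immune association

Feature associations are Spearman correlations with BH adjustment
across features. Infiltration scores are deliberately generic: a
population is any user-supplied marker set and its score is the
arithmetic mean of marker expression per sample — the published
marker-panel tools' exact gene lists and log/geometric-mean details are
not reproduced, only the qualitative use (relative infiltration versus
the signature score). Median splits assign ties to "low" (high =
strictly greater than the median) on both the signature and TMB axes;
the four quadrant labels (HGHT/HGLT/LGHT/LGLT) partition the samples
exactly. Pairwise group comparisons are two-sided Mann–Whitney tests
with BH adjustment across pairs; groups with fewer than 2 samples are
skipped with a warning.

## Batch adjustment

The merge step implements the parametric empirical-Bayes location/scale
scheme: per gene, standardize by the batch-size-weighted grand mean and
pooled variance; estimate per-(batch, gene) location `γ` and scale `δ`;
shrink with a normal prior on `γ` and an inverse-gamma prior on `δ`
(method-of-moments hyperparameters, fixed-point iteration to relative
tolerance `1e-6`, at most 500 iterations); remove the batch effects and
back-transform. Input must be log-scale expression. One convention was
fixed deliberately: **population (1/n) variance denominators are used
consistently** for both the pooled variance and the per-batch scale
estimates. Mixed conventions (1/N pooled with ddof-1 batch variances)
leave the `eb=False` adjustment slightly non-idempotent; the consistent
choice makes it exactly idempotent and makes each batch's
post-adjustment mean and population variance equal the grand mean and
pooled variance to numerical precision. Zero-pooled-variance genes pass
through untouched with a warning; a single batch is an identity map;
batches of fewer than 2 samples are an error. No biological covariates
are preserved during adjustment (cohorts are merged unconditionally);
this is config-exposed only in the sense that callers can pre-residualize
if needed.

## Response modelling

The split draws round-half-up(`0.8·n`) training samples, allocated per
response class by largest remainder (so 772 samples give 618/154 and a
5R/5NR cohort of 10 gives a 4/4 training set); designated held-out
cohorts bypass the split untouched. Response vocabularies are expected
to be pre-mapped to R/NR by the caller (the conventional mapping
CR/PR→R, SD/PD→NR is the documented default for callers with RECIST
labels).

Seven algorithms are trained: kernel naive Bayes, kNN, random forest,
RBF SVM, gradient-boosted logistic stumps (a LogitBoost analogue),
AdaBoost trees, and a correlation nearest-centroid rule. The kernel
naive Bayes is implemented here with the semantics of its R namesake:
per-class, per-feature Gaussian kernel densities with Silverman
rule-of-thumb bandwidth times `adjust` (default 1), Gaussian densities
when `usekernel` is off, and Laplace smoothing `fL` (default 0) on the
class priors. The nearest-centroid rule is parameter-free (class
centroids, Pearson-correlation affinity) and therefore skips
cross-validation, training on the full training set. The SVM is scored
through a logistic map of its decision function — monotone in the
margin, so its AUC equals the raw SVM's and the 0.5 score threshold is
the SVM decision boundary. Hyperparameters come from small fixed grids
tuned by stratified 5-fold CV repeated 10 times with seeds derived from
one seed sequence; the selection metric is validation-set AUC.
Prediction scores are `P(NR)`; a score ≥ 0.5 labels the sample NR, and
model features absent from a matrix are imputed with training means
under a warning.

AUC is the tie-corrected Mann–Whitney statistic (concordant pairs plus
half ties over `n₊·n₋`), with a DeLong 95% CI from placement variances,
clipped to `[0, 1]`. The exact complement identity
`AUC(s) + AUC(−s) = 1` holds by construction. Survival comparisons use
Cox proportional hazards with Efron tie handling (via lifelines) on the
binary predicted-NR indicator, Wald CIs, and Kaplan–Meier medians; a
risk group without events is reported with a warning rather than an
error.

## CRISPR ranking

Gene-level log-fold change is the arithmetic mean over a gene's sgRNAs.
Within each dataset, gene LFCs are standardized with the sample
(ddof-1) standard deviation; the cross-dataset statistic is the mean Z
over the datasets that recorded the gene — missing (gene, dataset)
pairs are simply skipped, and a `min_presence` floor (default 1) can
exclude sparsely measured genes. More negative mean Z = stronger
immune-resistance candidate. Ranks ascend in mean Z with lexicographic
tie-breaking for determinism, and dataset summation order is
canonicalized so the ranking is exactly invariant to input order.
Top-fraction cuts take the first `floor(f·N)` genes, which reproduces
the 1,125 / 2,250 / 4,501 cut sizes on a 22,505-gene universe.
Enrichment of a signature among top-ranked genes is the one-sided
hypergeometric upper tail by default (two-sided Fisher available); the
signature is restricted to the ranking universe before testing.

## Synthetic data

The generators produce the statistical structure each stage assumes,
with the generating truth returned alongside the data and never
re-inferred from it; all are bit-reproducible given (parameters, seed).

* **Single-cell**: negative-binomial counts with fixed dispersion 0.5
  (variance `μ + 0.5μ²` — minimal realistic overdispersion for
  rank-based downstream statistics), log-normal per-gene base means
  (median 2 counts, log-sd 1) and log-normal library factors (log-sd
  0.3). Each cell carries a latent glycolysis activity
  `a ~ Uniform(0,1)` (uniform rather than normal: the downstream
  pipeline is Spearman-based, so only ranks matter). In malignant
  cells, planted-program gene means are multiplied by
  `exp(logfc) · a^c / E[a^c]`, `c = corr_strength`; the mean-one
  normalization of the `a^c` factor makes `logfc` the mean log-fold
  overexpression independent of `c`, and the dependence on `a`
  vanishes as `c → 0`.
* **Bulk ICI cohorts**: log-scale Gaussian expression; non-responders'
  signature genes shifted additively; per-(cohort, gene) batch effects
  (additive location sd 1.0, log-normal scale sd 0.2 by default);
  exponential survival with baseline median 20 months, non-responder
  hazard multiplied by the true hazard ratio, and administrative
  censoring at the 70th percentile of event times so both events and
  censoring always exist.
* **CRISPR screens**: per-dataset gene effects `~ N(0,1)`, planted
  resistance genes shifted by `lfc_shift` (a warning if non-negative),
  3 sgRNAs per gene scattering with sd 0.25, and independent
  per-(gene, dataset) dropout at `missing_rate`.

What the generators do **not** emulate: doublets, ambient RNA, zero
inflation beyond the NB model, gene–gene correlation structure,
per-cancer-type heterogeneity, non-proportional hazards, or sgRNA
efficiency differences. Passing tests therefore demonstrate correctness
of the algorithms under the stated statistical model, not performance
on real tumor atlases.

## Problem sizes and determinism

The verification suite uses 5 single-cell datasets of 2,000 genes ×
1,500 cells (50 planted genes), 5 bulk cohorts of 60 samples × 500
genes, and 10 screens of 2,000 genes — sizes at which every planted
signal is comfortably detectable by the stated thresholds while the
whole suite runs in a couple of minutes on one core. All randomness
flows through `numpy.random.SeedSequence`, so every result is
reproducible bit-for-bit from a single seed.

## Known limitations

* The ssGSEA scorer's min–max rescaling is matrix-relative; scores from
  different matrices are not comparable and the package never mixes
  them.
* The exact Spearman permutation null is enumerated only up to n = 10;
  between n = 11 and ~30 the t approximation is used even though it is
  mildly anti-conservative at the extremes.
* The correlation nearest-centroid probability is a linear map of a
  correlation difference — fine for ranking (AUC) and thresholding,
  not a calibrated probability.
* ComBat here has no reference-batch mode and no covariate
  preservation; count-level (sequencing-depth-aware) batch models are
  out of scope.
* Gene identifiers are treated as upper-case symbols; no cross-space
  (e.g. Ensembl) conversion is attempted.
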