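# Methods

## Problem and model

odscore addresses single-sample outlier detection in a genes × samples
expression matrix `X` (`x_ij`, gene `i = 1..n`, sample `j = 1..m`) on a
log-like scale. The implicit model is that for most genes the m samples
are exchangeable draws from a common per-gene distribution, while an
aberrant gene in one sample carries an additive shift of several
log-units. All five statistics score the divergence of one cell from its
row; none models gene–gene correlation, and all assume the samples'
*overall* intensity distributions are comparable (quantile-normalization-
style preprocessing upstream). When that global comparability fails, the
weighted variants and the covariate adjustment are the mitigation tools.

## Statistics

Per gene row, the Zscore standardizes by (mean, sd) and the Rscore by
(median, scaled MAD). Choices fixed here:

* sd uses the m−1 denominator; MAD is scaled by 1.4826 (consistent for the
  sd under normality), both matching the defaults of the statistical
  environments practitioners use for these scores. The MAD constant is a
  parameter of `rscore`.
* Degenerate scale (sd = 0 or MAD = 0): policy `flag` (default) scores the
  row NaN and records it in `flagged_genes`; `error` raises. Silently
  emitting huge finite scores would corrupt rankings, so neither is done.

The outlying degree of sample `j` for gene `i` sums the `k` smallest
absolute differences `d_ij'j = |x_ij − x_ij'|` over the other samples.
WODa re-weights the `k` unweighted-nearest differences by the sample
dissimilarities `w_jj'` (Euclidean distance between sample columns over
all genes — no gene exclusion) and normalizes by the sum of the selected
weights, i.e. a weighted mean. WODb scales every difference by
`w_jj' / Σ_{j'≠j} w_jj'` *before* selecting and summing the `k` smallest.
Consequences worth knowing:

* With constant positive weights, WODa = OD/k and WODb = OD/(m−1)
  elementwise, so per-gene sample rankings coincide with OD (asserted in
  tests to 1e-12).
* WODa multiplies distances by the raw dissimilarity `w_jj'`, i.e. the
  *more* dissimilar neighbor contributes more weight. This is the
  definition as specified, kept exactly; an inverse-weighted variant may
  look more natural for down-weighting globally divergent samples but is
  deliberately not implemented. WODb's normalization by the total
  off-diagonal weight does provide the intended attenuation when several
  samples are divergent, which is where it earns its keep in the
  benchmark.
* Neighbor ties (equal `d`, or equal weighted `d`): stable sort with the
  original sample-index order as tie-break, so results are deterministic
  across platforms. In WODb's ordering the division by `Σ_{j'≠j} w_jj'`
  is a positive per-sample constant and is skipped during sorting (it
  cannot change the order) but retained in the summed values.
* WODa with a zero weight-sum over the selected neighbors falls back to
  the unweighted mean of the k distances (the equal-weights limit) and
  flags the gene. WODb with an all-zero weight row raises: every sample
  pair is identical and the score is undefined.
* Default `k` is floor(m/2); adequate for cohorts above ~10 samples, with
  little gain above that value and losses mainly at much smaller `k`
  (see `examples/choose_k.py`).

Scores of the OD family are reported unsigned; `assign_sign` attaches
sign(x_ij − median(x_i)) as a separate channel. The median (not the mean)
is used as the reference because it is robust to the outlier being
assessed; at exact equality the sign is 0.

## Significance

The empirical rank p-value of a designated gene `g1` within one evaluated
sample is

    p = [ #{i≠g1: T_i > T_g1} + ½ #{i≠g1: T_i = T_g1} ] / (n − 1)

with `T` the absolute statistics of all n genes for that sample. This is a
*gene-wise, within-sample* null — the target is referred to the other
genes of the same sample, not to permutations across samples — hence the
n − 1 denominator. It is exactly uniform under gene exchangeability and
invariant to monotone transforms of `T`. It is meaningful when the truth
(simulation) designates `g1`; for applied data the package reports ranks,
not per-gene p-values, because no principled applied analogue of `g1`
exists.

The empirical FDR with truth set `G` (|G| = S) is the fraction of the
top-S ranked genes not in `G`. Ranking is by decreasing absolute
statistic with gene index as tie-break (the same deterministic order as
`rank_genes`); values lie on {0, 1/S, …, 1}. This is a truth-referenced
top-S false fraction, not a Benjamini–Hochberg-style estimate.

`rank_genes` ranks by absolute statistic by default (matching the
two-sided p-value); `direction="positive"` restricts to up-regulated
genes, the primary use case.

## Simulation framework

One benchmark condition (`SimulationScenario`) draws `n_genes × n_samples`
i.i.d. values from either Normal(mean 7, sd 1) — the low-variability
extreme, resembling quantile-normalized array data — or a noncentral t
(df 15, noncentrality 7, standard `N(ncp,1)/sqrt(χ²_df/df)`
parameterization), the high-variability extreme. Note the noncentral t's
mean is ≈7.38 and its sd ≈1.27, not (7, 1); that inflation *is* the
intended stress. Defaults: 10,000 genes, 20 samples, S = 100 true
positives, k = 9, alpha = 0.05.

Injection: the outlier effect adds +`effect_size` (3/4/5 in the standard
grid) to S randomly chosen genes of one sample; power designates the first
of them as the evaluated gene, and a `single_gene_power` switch injects
only that one (both modes give near-identical power at the default truth
fraction of 1%; the S-gene default keeps power and FDR on one simulation
design). The optional technical factor adds −2 units to one random gene
subset (shared across the affected samples, like an array-batch artifact
hitting the same probes) of 2,500 or 7,500 genes in 1 or 3 samples;
`includes_true_outlier` forces the truth into the affected sets — the
hard case. Caution when scaling down: keep S/n_genes ≈ 1%, otherwise the
other injected genes crowd the p-value denominator and power saturates
near alpha.

Power is the fraction of iterations with p < alpha for the designated
gene, with a 0.95 Wilson score interval; FDR is the mean top-S false
fraction with a 0.95 normal-approximation interval on the mean. (The CI
constructions are this package's choices and are recorded in the result
metadata.) Randomness: one master seed spawns an independent
`SeedSequence` child per iteration, so results are bit-for-bit
reproducible and independent of any execution order; `k_sweep` re-uses
the same children across k values so the curves share their cohorts.

## Covariate adjustment

`adjust_covariates` fits, per gene, ordinary least squares of expression
on an intercept plus the named covariates (categorical covariates
treatment-coded against the first sorted level) and returns the residual
matrix. OLS, not robust regression, is the deliberate choice — the
adjustment targets broad group shifts, and a handful of outlier genes
barely perturbs per-gene fits at cohort scale; a robust variant would be
a natural extension. Scores on residuals are invariant to any
covariate-explainable offset and the operation is idempotent (to 1e-10).
Weight matrices for the WOD variants are recomputed from the residual
matrix, not carried over from the raw data. Rank-deficient designs are
rejected with the collinear columns named.

## Synthetic data and what the tests show

The bundled generator (`odscore.fixtures`) emulates a small, clean,
quantile-normalized cohort: tight Normal(7, 0.35) baseline, three planted
single-sample outliers at +3/+4/+5, a +1.5 gender block shift, and one
gene dysregulated in two samples. It reproduces the *structure* of real
use cases (effect-size categories, covariate confounding, shared
dysregulation) but none of the messiness of real arrays: no gene–gene
correlation, no heteroskedastic probe noise, no batch structure beyond
what is injected, and i.i.d. genes throughout. Passing tests therefore
demonstrate correctness of the statistics and the claimed behavior under
the stated generative model — not performance on any particular real
dataset, where effect sizes, variability and confounding must be judged
per cohort.

## Problem sizes

The verification suite runs the full 10,000 × 20 benchmark at 600
iterations per scenario (the acceptance layer) and scaled-down variants
(400–1,000 genes, tens to hundreds of iterations) for distributional and
monotonicity checks; 600 iterations put the Monte-Carlo standard error of
a power estimate near 0.016, tight enough for the bounds asserted.

## Known limitations

Univariate only — no pathway-level or multivariate outlier scores, no
mixture-model subgroup detection, and no surrogate-variable estimation
for unknown confounders. The empirical FDR requires a known truth set and
is a simulation instrument, not an applied error estimate. The weighted
variants assume the dissimilarity structure is informative; with few
genes the weight matrix itself is noisy.
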