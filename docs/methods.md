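# Methods

This note documents the statistical model behind `permdeg`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Normalization

Raw counts are scaled with trimmed mean of M-values (TMM). For sample *j*
against a reference sample *r* (the sample whose 75th-percentile count
fraction is closest to the across-sample mean), per-gene
M = log2((x_gj/N_j)/(x_gr/N_r)) and A = ½·log2((x_gj/N_j)(x_gr/N_r)) are
computed on count fractions; genes with a zero in either sample are
excluded from factor estimation only (never from the expression matrix).
M-values are trimmed 30% on each side and A-values 5%; the factor is the
weighted mean of the surviving M-values with inverse asymptotic-binomial-
variance weights, and factors are rescaled to geometric mean 1. These are
the canonical published TMM choices; our factors agree with the edgeR
reference implementation to 1e-10 (cross-checked in the test suite via
Rscript). Because the precision weights depend on absolute counts, exact
scale-equivariance holds only approximately (~2% at a 3× depth change);
this matches the reference implementation.

Expression values are `log2(count / s_j + 1)` where
`s_j = N_j · TMM_j / geomean` is the relative effective size factor.
Dividing before the pseudocount (rather than shifting the log2(count+1)
matrix by −log2 s_j) makes samples that differ only in depth normalize to
*identical* columns at machine precision; the shift form is also provided
(`apply_factors`) and is equivalent for large counts.

## The integrative test

Per gene, on normalized log2 expression: the log2 fold change
(group2 − group1 means) and the pooled-variance Student's t
(df = n₁+n₂−2; the pooled variance is floored at 1e-8 so constant genes
yield t = 0 rather than NaN). Welch's t is deliberately not used: at
n = 2 per group its degrees-of-freedom estimate is degenerate.

**Permutation null.** All C(n₁+n₂, n₁) group-size-preserving relabellings
are enumerated; the identity labelling is removed, and in balanced designs
each labelling and its group-swap mirror collapse to one split class
(their statistics differ only in sign, which two-sided ranking ignores).
For 2 vs 2 this leaves 2 splits. Both statistics are recomputed under
every retained split and pooled **across genes** into one null multiset
per statistic: with ≤ 2 usable permutations per gene, a per-gene null
cannot resolve p below 1/3, while the pooled null reaches
1/(2·n_genes + 1). A `null_scope="per_gene"` option exists for
sensitivity analysis. Designs too large to enumerate (assignments beyond
`max_exhaustive`, default 10,000) fall back to a seeded Monte-Carlo
subsample of distinct splits.

**Empirical p-values.** Two-sided with add-one smoothing:
p = (#{|x| in null ≥ |obs|} + 1)/(N+1), so every p lies on the grid
k/(N+1) and is never 0 — which keeps the normal quantiles finite.

**Combination and calling.** z_i = Φ⁻¹(1−p_i) with p clipped to
[1/(N+1), 1−1/(N+1)]; p_comb = 1 − Φ((z_t+z_lfc)/√2), equal weights.
A gene is a DEG iff p_comb ≤ α (default 0.05) *and* |log2FC| ≥ 0.58
(1.5-fold); both inequalities inclusive. Direction is the sign of log2FC.

## Calibration: a documented limitation

The two component p-values are individually well calibrated (measured
P(p ≤ 0.05) of 0.052 and 0.055 on a 2000-gene null simulation), but t and
log2FC share their numerator, so corr(z_t, z_lfc) ≈ 0.8 at 2 vs 2 and the
equal-weight Stouffer combination of correlated z-scores is
**anti-conservative**: the measured fraction of null genes with
p_comb ≤ 0.05 is ≈ 0.10–0.12. The inflation is structural — it persists
for homoscedastic data with no mean–variance relationship — not an
artifact of the count model. Consequently, in the
spike-recovery simulation (10,000 genes, 10% spiked at |log2FC| = 2,
NB dispersion 0.1) the dual-threshold call set reaches sensitivity ≈ 0.94
but an FDR ≈ 0.5: at dispersion 0.1 the per-gene log2-scale SD has an
asymptotic floor √ln(1.1)/ln2 ≈ 0.44, so a substantial share of null
genes clears the 0.58 fold-change cutoff by chance and the
anti-conservative combined p admits them. `integrative_test(..., bh=True)`
applies Benjamini–Hochberg to the combined p-values before calling;
on the same simulation this yields sensitivity ≈ 0.80 at FDR ≈ 0.18 and
zero null-simulation DEGs (all of these numbers are recomputed by
`scripts/acceptance.py`). Users who need calibrated error control should
use `bh=True`; the default reproduces the classical procedure.

## Synthetic data generator

Counts are negative binomial with variance m + φm² (φ = `dispersion`,
default 0.1, typical of bulk RNA-seq; the φ → 0 limit is Poisson and is
tested). Gene means are log-normal (meanlog 4.0, sdlog 1.5: median ≈ 55
counts with a heavy right tail), reproducing the dynamic range of real
libraries without external data. Library-size factors default to an
unequal geometric ladder from 0.8 to 1.25 (geometric mean 1), emulating
unequal sequencing depths. A `de_fraction` of genes (rounded half-up to
an exact count) receives a multiplicative 2^(±`de_log2fc`) shift of the
second condition's mean, signs balanced half up / half down and assigned
by the seed; the per-gene truth table records `is_de` and `true_log2fc`.
Identical configurations reproduce byte-identical matrices.

What the generator does **not** emulate: batch effects, gene–gene
correlation, length/GC biases, alignment and quantification noise, or
isoform structure. Passing tests therefore establish the correctness and
calibration of the statistics under the assumed count model, not
robustness to those real-data artifacts.

## Enrichment and network conventions

Enrichment is one-sided (over-representation): P(X ≥ overlap) under the
hypergeometric distribution with the **tested gene universe** (all genes
in the expression matrix, not the genome) as population; sets are first
intersected with the universe. No multiple-testing correction by default
(sets with raw p < 0.05 are flagged), BH optional. Category proportions
split a gene over its k matching categories with weight 1/k, so
proportions (with "other" for unmatched genes) sum to one.

The interaction subnetwork keeps the selected genes plus their direct
interactors **present in the expression data**, so every node has a
defined log2FC; self-loops are dropped and duplicate edges merge with the
union of their source-database labels. Node grouping uses the
lexicographically first matching set name — a deterministic tie-break.
Graphs are undirected; no layout coordinates are computed.

## Numerical and interface choices

- Variance floor 1e-8 on the pooled variance (constant genes → t = 0).
- DEG thresholds and trim fractions are parameters, defaulted as above.
- Problem sizes used by the validation scripts — 2,000 genes for the null
  calibration and 10,000 for spike recovery — give binomial standard
  errors below 0.005 on the measured rates while keeping a full run in
  seconds.
- The phenotype metric is exact arithmetic: LBM = weight − volume × 0.9
  (g, cm³, g/cm³); the density is overridable.
- Pipeline runs are pure functions of (inputs, config, seed); the
  manifest records SHA-256 hashes of all inputs and outputs and contains
  no timestamps, so reruns are byte-identical and diffable.
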