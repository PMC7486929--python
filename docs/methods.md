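# Methods

This note records the model implemented by `depthscore`, the conventions
and defaults it adopts, what the synthetic data generator does and does
not emulate, and the numerical choices made along the way.

## 1. The DEPTH score

### Model

Input is a genes × samples expression matrix on the `log2(x + 1)` scale
(the package transforms raw values on request and tracks the scale with
a tag so a matrix cannot be transformed twice). For tumor sample `s`
with expression `e_is` over genes `i = 1..m`:

```
r_i   = mean of gene i over the reference samples
d_i   = (e_is − r_i)²
DEPTH = sqrt( Σ_i (d_i − mean(d))² / (m − 1) )
```

Two reference modes exist:

- **normal-referenced** — `r_i` is the mean over the `n` normal
  controls; used whenever normals are present;
- **tumor-referenced** — `r_i` is the mean over all `t` tumor samples,
  the scored sample included; the fallback when a cohort has no normals.
  A leave-one-out variant (scored sample excluded from its own
  reference) is available but not the default.

The `auto` mode picks normal-referenced when any normal is labeled.

### Properties the implementation guarantees

- A tumor equal to the reference, or offset from it by any constant,
  scores exactly 0 (the squared deviations are then constant across
  genes, so their standard deviation vanishes). A lone tumor scored
  tumor-referenced is its own reference and scores 0.
- Scaling every deviation by `c` scales the score by `c²` — the score is
  a second-moment statistic of deviations, not of expression.
- The score is invariant under gene reordering.

### Assumptions and scope

- Scores are comparable *within* a cohort scored against one reference;
  comparing scores across cohorts with different references or
  platforms is not meaningful without calibration.
- The score is intended for transcriptome-scale input. Below 1000 genes
  the standard deviation over genes is noisy; the package warns (but
  does not refuse) in that regime, since small matrices are legitimate
  in tests and demos.
- Missing values are rejected rather than imputed; imputation policy is
  the caller's responsibility.

## 2. Cohort summaries

**Shannon diversity index (SDI).** Scores are histogrammed into
`n_intervals = 22` half-open unit bins `[i, i + 1)` for `i = 1..22`,
covering `[1, 23)`. With bin proportions `p_b`, `SDI = −Σ p_b log2 p_b`
(bits). Scores below 1 or at/above 23 are clamped into the first/last
bin and the count of clamped samples is reported, so the caller can see
when the default grid does not fit their cohort. Bin origin, width and
count are all parameters.

**Clone number.** Each sample's score is divided by the cohort minimum
and rounded half-up, so the minimum-scoring sample is clone 1 and the
assignment is invariant to rescaling all scores by a common factor. A
non-positive minimum is an error (the ratio is then undefined); in
practice scores are positive whenever any gene deviates.

## 3. Signature scoring

**Mean score.** Per-sample mean of log2 expression over the gene set.
Genes absent from the matrix are dropped with a warning; an empty
intersection is an error naming the set.

**CD8+/Treg ratio.** Signature means are computed on the *linear* scale
(log2 values are inverted as `2^v − 1`), then
`log2((mean_CD8 + 1) / (mean_Treg + 1))` with pseudocount 1, so the
ratio of cytotoxic to regulatory T-cell signal is symmetric around 0
and finite for empty signal.

**ssGSEA.** For one sample, genes are ranked by expression (average
ranks for ties) and walked from highest to lowest. The running sum adds
the weighted in-set empirical CDF — weights `|rank|^alpha`,
`alpha = 0.25` by default — and subtracts the unweighted out-of-set
ECDF; the score is the sum of the running statistic over all positions.
Optional normalization divides every sample's score by the max − min
score across samples. A set covering every gene is rejected (the
out-of-set ECDF is undefined); a constant sample scores 0 with a
warning.

## 4. Pseudo-tumor simulation

**Max-pooling.** A pseudo-tumor's per-gene expression is the maximum
over its member cells — the bulk profile of a mixture is dominated, per
gene, by whichever clone expresses it most.

**Size series.** Pseudo-tumors of `5, 10, …, 5k` cells with
`k = round_half_up(total / 5)` capped at `floor(total / 5)`, each drawn
uniformly without replacement, draws independent across samples. The cap
keeps the largest sample drawable without replacement when `total` is
not a multiple of the step.

**Diversity series.** `m` pseudo-tumors of `m` cells each; sample `i`
draws its cells from exactly `i` distinct groups chosen uniformly among
groups holding enough cells, the `m` cells split as evenly as possible
with remainders going to the groups drawn first.

**Scoring a series.** `score_series` scores the pooled samples
tumor-referenced with the *source cells included in the cohort*, all
labeled tumor (a cell panel has no normal controls). This is a
deliberate design choice: the cells anchor the reference mean at the
population average, so a pseudo-tumor's score measures how far
max-pooling has pushed it from a typical cell, and grows monotonically
as more — or more diverse — cells are pooled. Scoring the pooled series
alone would instead place the tumor-mean reference among the saturated
large pools and invert the relationship.

### The synthetic cell generator

`synthetic_cells(n_groups, cells_per_group, n_genes, group_effect_sd,
noise_sd, seed)` emulates a panel of cell lines from distinct cancer
types, on the log2 scale:

- a shared per-gene baseline ~ Normal(5, 1), truncated at 0;
- per group, a sparse **marker block**: the genes are partitioned into
  `n_groups` disjoint blocks and each group's template elevates its own
  block by `|Normal(0, 1.5 · group_effect_sd)|` — type-specific marker
  expression;
- per group, a dense effect ~ Normal(0, 0.25 · group_effect_sd) on all
  genes — diffuse between-type differences;
- per cell, i.i.d. Normal(0, noise_sd) noise; all values truncated at 0.

The sparse marker structure is the load-bearing part: the set of genes
a max-pooled pseudo-tumor elevates above baseline grows with the
diversity of its members, which is exactly the signal heterogeneity
scoring should detect. What the generator does **not** emulate:
count-based sampling noise (values are Gaussian around the template),
single-cell dropout, library-size variation, correlated gene modules
within a block, or continuous differentiation gradients between groups.
It is a controlled test bed for the scoring pipeline, not a realistic
scRNA-seq simulator.

Defaults used throughout the experiments: 20 groups × 25 cells, 1500
genes, `group_effect_sd = 2.0`, `noise_sd = 0.5`.

## 5. Statistics

**Spearman correlation.** Pearson correlation of average ranks. For
`n ≤ 9` the p-value is exact: all `n!` rank permutations are enumerated
and the two-sided tail on `|rho|` counted (with 1e-12 slack against
floating-point ties). For larger `n`, the t-approximation
`t = rho · sqrt((n − 2) / (1 − rho²))` with `n − 2` degrees of freedom;
`|rho| = 1` gives p = 0.

**One-sided Mann–Whitney U.** `U` from the average-rank sum of the
first sample. When `n1 · n2 < 20` the p-value is exact and tie-aware:
all `C(n1 + n2, n1)` group assignments of the pooled values are
enumerated and `p = P(U* ≥ U_obs)` under the permutation null (so two
identical samples give p slightly above 0.5 — the observed value sits
in its own tail). Otherwise, the continuity-corrected normal
approximation with tie correction (scipy).

**FDR.** Benjamini–Hochberg step-up (statsmodels), returning adjusted
p-values clipped to 1 that preserve the ordering of the raw p-values.

## 6. Numerical conventions

- **Rounding** of clone numbers and series counts is half-up
  (`floor(x + 0.5)`), not banker's rounding, so `2.5 → 3` — the
  convention a reader doing the arithmetic by hand expects.
- **Standard deviations** use the `m − 1` (sample) denominator
  everywhere.
- **ssGSEA tie-break**: among tied expression values, genes are ordered
  lexicographically by gene id, making the score invariant to the input
  row order even with ties.
- **Exact-vs-approximate thresholds** (`n ≤ 9` for Spearman,
  `n1 · n2 < 20` for Mann–Whitney) keep the exact branches well under a
  second while covering the sample sizes where the asymptotics are
  poorest.
- **File round-trips** write floats with 12 significant digits, so a
  write/read cycle preserves values to ~1e-11 relative error.
- Duplicate gene rows on input are collapsed by the per-sample maximum
  (matching the max-pooling convention); duplicate sample columns are an
  error, detected on the raw header before parsing.
- All simulation randomness flows through `numpy.random.default_rng`
  seeds, so every experiment is reproducible from a single integer.

## 7. Limitations

- The score conflates subclonal diversity with any other source of
  within-tumor expression dispersion (stromal or immune admixture,
  technical noise); it is a proxy for ITH, not a clone caller.
- Tumor-referenced scoring depends on cohort composition: adding or
  removing samples shifts the reference and hence every score.
- The SDI default grid assumes scores of order 1–23; cohorts outside
  that range need a custom origin/width (the clamp counter flags this).
- Clone numbers inherit the noise of the minimum-scoring sample; a
  single outlier with a near-zero score inflates every ratio.
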