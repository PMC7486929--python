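# depthscore

Quantify **intratumor heterogeneity (ITH)** from bulk gene-expression
profiles with the DEPTH score, plus the cohort summaries, signature
scores, simulation experiments, and statistical tests that usually
accompany it.

## The scientific problem

A tumor is rarely one clone. Distinct subclones inside the same tumor
differ in their transcriptomes, and that internal diversity — intratumor
heterogeneity — predicts therapy resistance and poor outcomes. Most ITH
measures need DNA sequencing or single-cell data; DEPTH asks how much
heterogeneity can be read directly from an ordinary bulk expression
matrix.

The idea: a homogeneous tumor deviates from a reference expression
profile in a *consistent* way, while a heterogeneous one mixes clones
whose deviations vary strongly from gene to gene. DEPTH therefore
measures the *spread* of a tumor's per-gene deviations.

## The model

Expression values are `log2(x + 1)`-transformed. For tumor sample `s`
over genes `i = 1..m`:

1. Compute each gene's reference mean `r_i` — the mean over normal
   control samples when any are present, otherwise the mean over all
   tumor samples (the scored sample included).
2. Form the squared deviations `d_i = (e_is − r_i)²`.
3. The DEPTH score of `s` is the sample standard deviation (with the
   `m − 1` denominator) of `d_1, …, d_m`.

A tumor identical to the reference — or offset from it by any constant —
scores exactly 0; doubling every deviation quadruples the score. Higher
scores mean greater ITH.

Around the score the package provides:

- **Shannon diversity index** of a cohort's score distribution over 22
  unit-width bins covering scores in `[1, 23)` (out-of-range scores are
  clamped into the end bins and counted);
- **clone numbers**: each sample's score divided by the cohort minimum,
  rounded half-up, so the least heterogeneous sample is clone 1;
- **signature scoring**: per-sample mean expression of a gene set,
  single-sample GSEA (ssGSEA, weighted-ECDF running sum, `alpha = 0.25`),
  and the log2 ratio of CD8+ T-cell to regulatory T-cell signature means;
- **pseudo-tumor simulation**: max-pooling cells into artificial tumors
  for the size-series and diversity-series experiments, with a synthetic
  single-cell generator so no external data download is needed;
- **statistics**: Spearman correlation (exact permutation p-value for
  n ≤ 9), one-sided Mann–Whitney U (exact enumeration for small
  samples), and Benjamini–Hochberg FDR adjustment.

## Worked example

Build a small synthetic cohort — four cells of one group act as normal
controls, six pseudo-tumors max-pool 2 to 12 randomly drawn cells — and
run the full scoring pipeline:

```python
import numpy as np
import pandas as pd
import depthscore as ds

# synthetic single-cell population: 5 groups x 8 cells, 1500 genes (log2 scale)
rng = np.random.default_rng(0)
pop = ds.synthetic_cells(5, 8, 1500, group_effect_sd=2.0, noise_sd=0.4, seed=0)

normals = [c for c in pop.cell_ids if pop.group_of[c] == "group1"][:4]
tumors = [ds.max_pool(pop, list(rng.choice(pop.cell_ids, size=k, replace=False)),
                      f"tumor{k}")
          for k in (2, 4, 6, 8, 10, 12)]
data = pd.concat([ds.pooled_expression_matrix(pop, tumors), pop.data[normals]],
                 axis=1)
expr = ds.ExpressionMatrix(data, scale="log2")
labels = ds.SampleLabels({**{t.sample_id: "tumor" for t in tumors},
                          **{n: "normal" for n in normals}})

scores = ds.depth_scores(expr, labels)
print(scores.to_string(index=False))

sdi = ds.shannon_diversity(scores["depth_score"])
print(f"\nShannon diversity of the scores: {sdi.sdi:.4f} bits "
      f"({sdi.n_samples} samples, {sdi.n_clamped} clamped)")

clones = ds.clone_numbers(scores)
print(clones.table.to_string(index=False))
```

Output:

```
sample_id  depth_score reference_mode  m_used
   tumor2    11.904182    normal_mean    1500
   tumor4     8.057589    normal_mean    1500
   tumor6    13.253445    normal_mean    1500
   tumor8    11.625212    normal_mean    1500
  tumor10    13.041534    normal_mean    1500
  tumor12    14.135594    normal_mean    1500

Shannon diversity of the scores: 1.9183 bits (6 samples, 0 clamped)
sample_id  clone_number
   tumor2             1
   tumor4             1
   tumor6             2
   tumor8             1
  tumor10             2
  tumor12             2
```

## Command line

The `depth` entry point exposes the same pipeline on TSV/CSV files:

```
depth score      --expr expr.tsv --labels labels.tsv --out scores.tsv
depth sdi        --scores scores.tsv --out sdi.tsv
depth clones     --scores scores.tsv --out clones.tsv
depth signatures --expr expr.tsv --gmt sets.gmt --method ssgsea --out sig.tsv
depth synth-cells --n-groups 20 --cells-per-group 25 --n-genes 1500 \
                  --seed 42 --out-prefix pop
depth simulate   --cells pop.expr.tsv --groups pop.groups.tsv \
                  --mode diversity --m 20 --seed 42 --out-prefix sim
depth correlate  --scores scores.tsv --covariate cov.tsv --out corr.tsv
depth compare    --scores scores.tsv --groups grp.tsv --out cmp.tsv
```

Expression files are genes × samples with a header row of sample ids;
label files are two-column `sample_id <tab> tumor|normal`. `--help` on
any subcommand lists all options.

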