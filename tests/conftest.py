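"""Shared fixtures and independent brute-force oracles.

The oracles implement the published definitions literally (scalar loops,
no vectorization) so they stay independent of the library code they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from depthscore import ExpressionMatrix, SampleLabels


def depth_scores_oracle(values, tumor_cols, normal_cols, mode):
    """Literal term-by-term evaluation of the heterogeneity score.

    ``values`` is an m x s nested list/array; ``mode`` is 'normal' or
    'tumor'. Returns one score per tumor column, computed with plain Python
    loops exactly as the displayed definition reads: per-gene deviation from
    the group mean, squared, then the sample SD over genes of the squares.
    """
    m = len(values)
    ref_cols = normal_cols if mode == "normal" else tumor_cols
    scores = []
    for ts in tumor_cols:
        deltas = []
        for i in range(m):
            ref = 0.0
            for j in ref_cols:
                ref += values[i][j]
            ref /= len(ref_cols)
            deltas.append(values[i][ts] - ref)
        d2 = [d * d for d in deltas]
        mean_d2 = sum(d2) / m
        acc = 0.0
        for x in d2:
            acc += (x - mean_d2) ** 2
        scores.append(math.sqrt(acc / (m - 1)))
    return scores


def ssgsea_oracle(values, gene_ids, set_genes, alpha):
    """Step-by-step running-sum enrichment for one sample.

    Average ascending ranks computed by counting; genes walked from highest
    to lowest rank (ties broken by gene id); weighted in-set ECDF
    (|rank|**alpha) minus unweighted out-of-set ECDF, summed over positions.
    """
    m = len(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    order = sorted(range(m), key=lambda i: (-ranks[i], gene_ids[i]))
    in_set = [gene_ids[i] in set_genes for i in order]
    w = [abs(ranks[i]) ** alpha for i in order]
    denom_in = sum(wi for wi, s in zip(w, in_set) if s)
    n_out = sum(1 for s in in_set if not s)
    p_in = p_out = 0.0
    total = 0.0
    for wi, s in zip(w, in_set):
        if s:
            p_in += wi / denom_in
        else:
            p_out += 1.0 / n_out
        total += p_in - p_out
    return total


def make_expression(values, gene_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, dtype=float)
    m, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(m)]
    sample_ids = sample_ids or [f"s{j}" for j in range(s)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale=scale
    )


def random_cohort(rng, m, t, n):
    """A random log2-scale cohort with t tumors and n normals."""
    values = rng.gamma(2.0, 2.0, size=(m, t + n))
    expr = make_expression(np.log2(values + 1.0))
    labels = SampleLabels(
        {f"s{j}": ("tumor" if j < t else "normal") for j in range(t + n)}
    )
    return expr, labels


@pytest.fixture
def small_cohort():
    """5 tumors + 3 normals over 40 genes, fixed seed."""
    return random_cohort(np.random.default_rng(7), m=40, t=5, n=3)
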