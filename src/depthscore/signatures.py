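"""Per-sample gene-set signature scores.

Three scoring schemes used alongside heterogeneity scores: the mean log2
expression of a marker set (immune signatures), the log2 ratio of the
CD8+ T-cell signature to the regulatory T-cell signature, and single-sample
gene-set enrichment (ssGSEA) for proliferation and stemness sets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix, GeneSet

__all__ = ["mean_signature_score", "stim_inhib_ratio", "ssgsea_score"]


def _intersect(expr: ExpressionMatrix, gene_set: GeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in expr.data.index]
    if not present:
        raise ValueError(
            f"gene set {gene_set.name!r}: no member gene found in the matrix"
        )
    dropped = [g for g in gene_set.genes if g not in expr.data.index]
    if dropped:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(dropped)} gene(s) absent from the "
            f"matrix and dropped: {dropped}",
            stacklevel=3,
        )
    return present


def mean_signature_score(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.DataFrame:
    """Per sample, the arithmetic mean of log2 expression over the marker genes.

    Genes absent from the matrix are dropped (with a warning); the number
    actually used is reported per row.
    """
    present = _intersect(expr, gene_set)
    scores = expr.data.loc[present].to_numpy(dtype=float).mean(axis=0)
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "signature_name": gene_set.name,
            "score": scores,
            "method": "mean_expression",
            "n_genes_used": len(present),
        }
    )


def stim_inhib_ratio(
    expr: ExpressionMatrix,
    cd8_set: GeneSet,
    treg_set: GeneSet,
    pseudocount: float = 1.0,
    linear: bool = True,
) -> pd.DataFrame:
    """log2 ratio of the CD8+ T-cell signature to the Treg signature.

    With ``linear=True`` (default) the per-sample means are taken on the
    linear scale, reconstructed from log2 values as 2**v - 1, and a
    pseudocount guards zero means:
    score = log2((mean_cd8 + pc) / (mean_treg + pc)). With ``linear=False``
    the log2-scale means are divided directly. Swapping the two sets negates
    the score.
    """
    cd8_present = _intersect(expr, cd8_set)
    treg_present = _intersect(expr, treg_set)
    if linear:
        lin = np.power(2.0, expr.data.to_numpy(dtype=float)) - 1.0
        lin = pd.DataFrame(lin, index=expr.data.index, columns=expr.data.columns)
        mean_cd8 = lin.loc[cd8_present].to_numpy().mean(axis=0)
        mean_treg = lin.loc[treg_present].to_numpy().mean(axis=0)
    else:
        mean_cd8 = expr.data.loc[cd8_present].to_numpy(dtype=float).mean(axis=0)
        mean_treg = expr.data.loc[treg_present].to_numpy(dtype=float).mean(axis=0)
    scores = np.log2((mean_cd8 + pseudocount) / (mean_treg + pseudocount))
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "signature_name": f"{cd8_set.name}/{treg_set.name}",
            "score": scores,
            "method": "log2_ratio",
            "n_genes_used": len(cd8_present) + len(treg_present),
        }
    )


def _ssgsea_sample(
    values: np.ndarray, in_set: np.ndarray, alpha: float, gene_ids: np.ndarray
) -> float:
    """Running-sum ssGSEA enrichment for one sample.

    Genes are walked in descending expression order, ties broken by gene id
    so the statistic is independent of gene order. The in-set ECDF is
    weighted by |rank|**alpha using average ascending ranks; the out-of-set
    ECDF is unweighted. The score is the sum over positions of their
    difference — the ssGSEA convention, not the single max-deviation of
    standard GSEA.
    """
    ranks = rankdata(values)  # ascending, average ties
    order = np.lexsort((gene_ids, -ranks))
    in_ordered = in_set[order]
    w = np.abs(ranks[order]) ** alpha
    w_in = np.where(in_ordered, w, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in
    out_ordered = ~in_ordered
    p_out = np.cumsum(out_ordered) / out_ordered.sum()
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores for every sample.

    Per sample, all m genes are ranked by expression (descending, average
    ranks for ties) and the score is the summed difference between the
    weighted in-set rank ECDF (weights |rank|**alpha) and the unweighted
    out-of-set ECDF. With ``normalize=True`` the scores are range-scaled:
    divided by (max - min) across the sample set (left unscaled when the
    range is zero).

    A sample whose expression is constant carries no ranking information
    and scores 0, with a warning.
    """
    present = _intersect(expr, gene_set)
    if len(present) >= expr.m:
        raise ValueError(
            f"gene set {gene_set.name!r} covers every gene in the matrix; "
            "the out-of-set ECDF is undefined"
        )
    in_set = expr.data.index.isin(present)
    gene_ids = expr.data.index.to_numpy(dtype=str)
    raw = np.empty(expr.s)
    for j, sample in enumerate(expr.sample_ids):
        v = expr.data[sample].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(
                f"sample {sample!r}: constant expression, ssGSEA score set to 0",
                stacklevel=2,
            )
            raw[j] = 0.0
        else:
            raw[j] = _ssgsea_sample(v, in_set, alpha, gene_ids)
    scores = raw
    if normalize:
        span = raw.max() - raw.min()
        if span > 0:
            scores = raw / span
    return pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "signature_name": gene_set.name,
            "score": scores,
            "method": "ssgsea",
            "n_genes_used": len(present),
        }
    )
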