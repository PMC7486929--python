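"""Per-sample intratumor-heterogeneity (DEPTH) scores.

A tumor's score is the sample standard deviation, across genes, of the
squared deviations of its log2 expression from a per-gene reference mean.
The reference is the mean over normal controls when the cohort has them
(normal-referenced mode) and the mean over all tumor samples otherwise
(tumor-referenced mode). Tumors whose genes deviate from the reference by a
shared amount score 0; tumors where some genes deviate strongly and others
not at all — asynchronous transcriptome alteration — score high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleLabels

__all__ = [
    "DeviationProfile",
    "NORMAL_MEAN",
    "TUMOR_MEAN",
    "reference_mean",
    "deviation_profile",
    "depth_score",
    "depth_scores",
]

NORMAL_MEAN = "normal_mean"
TUMOR_MEAN = "tumor_mean"

ReferenceMode = Literal["normal_mean", "tumor_mean"]

# below this gene count the squared-deviation SD is too noisy to rank tumors
MIN_RECOMMENDED_GENES = 1000


@dataclass
class DeviationProfile:
    """Per-gene deviations of one tumor sample from the reference mean."""

    sample_id: str
    deltas: np.ndarray
    reference_mode: ReferenceMode

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.deltas.ndim != 1:
            raise ValueError("deltas must be a 1-D vector")
        if not np.isfinite(self.deltas).all():
            raise ValueError("deltas contain non-finite values")


def _check_log2(expr: ExpressionMatrix) -> None:
    if expr.scale != "log2":
        raise ValueError(
            "expression matrix is not log2-scale; run log2_normalize first "
            "(or read it with scale='log2' if already transformed)"
        )


def reference_mean(
    expr: ExpressionMatrix, labels: SampleLabels, mode: ReferenceMode
) -> np.ndarray:
    """Per-gene mean expression over the reference group.

    ``normal_mean`` averages the normal controls; ``tumor_mean`` averages
    all tumor samples, including any sample later scored against it.
    """
    _check_log2(expr)
    labels.validate_against(expr)
    if mode == NORMAL_MEAN:
        ids = labels.normal_ids
        if not ids:
            raise ValueError(
                "no normal controls in the cohort; use mode='tumor_mean'"
            )
    elif mode == TUMOR_MEAN:
        ids = labels.tumor_ids
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    return expr.data[ids].to_numpy(dtype=float).mean(axis=1)


def deviation_profile(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    sample_id: str,
    reference: np.ndarray,
    reference_mode: ReferenceMode = TUMOR_MEAN,
) -> DeviationProfile:
    """Deviations of one tumor sample's expression from a reference vector."""
    _check_log2(expr)
    if sample_id not in expr.data.columns:
        raise KeyError(f"sample {sample_id!r} not in the expression matrix")
    if labels.assignments.get(sample_id) != "tumor":
        raise ValueError(f"sample {sample_id!r} is not labeled tumor")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (expr.m,):
        raise ValueError(
            f"reference length {reference.shape} does not match gene count {expr.m}"
        )
    deltas = expr.data[sample_id].to_numpy(dtype=float) - reference
    return DeviationProfile(sample_id=sample_id, deltas=deltas, reference_mode=reference_mode)


def depth_score(profile: DeviationProfile) -> float:
    """Sample standard deviation (ddof=1) of the squared deviations.

    Invariant to gene order; zero exactly when all squared deviations are
    equal (e.g. a gene-independent shift from the reference).
    """
    m = profile.deltas.size
    if m < 2:
        raise ValueError("DEPTH score needs at least 2 genes (divides by m - 1)")
    sq = profile.deltas**2
    return float(np.sqrt(np.sum((sq - sq.mean()) ** 2) / (m - 1)))


def depth_scores(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    mode: Literal["auto", "normal_mean", "tumor_mean"] = "auto",
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Score every tumor sample in the cohort.

    Parameters
    ----------
    mode
        ``auto`` picks the normal-referenced score when the cohort has at
        least one normal control, otherwise the tumor-referenced score.
    leave_one_out
        Tumor-referenced mode only: exclude the scored sample from the
        reference mean instead of the default all-tumor mean.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``depth_score``,
    ``reference_mode`` and ``m_used``, one row per tumor sample.
    """
    _check_log2(expr)
    labels.validate_against(expr)
    if mode == "auto":
        mode = NORMAL_MEAN if labels.normal_ids else TUMOR_MEAN
    if leave_one_out and mode != TUMOR_MEAN:
        raise ValueError("leave_one_out applies only to tumor-referenced scoring")
    if expr.m <= MIN_RECOMMENDED_GENES:
        warnings.warn(
            f"DEPTH scoring is intended for more than {MIN_RECOMMENDED_GENES} genes "
            f"(matrix has {expr.m}); scores may be unstable",
            stacklevel=2,
        )
    tumor_ids = labels.tumor_ids
    tumor_values = expr.data[tumor_ids].to_numpy(dtype=float)

    if leave_one_out:
        t = len(tumor_ids)
        if t < 2:
            raise ValueError("leave-one-out reference needs at least 2 tumor samples")
        total = tumor_values.sum(axis=1, keepdims=True)
        references = (total - tumor_values) / (t - 1)  # m x t, column per sample
        deltas = tumor_values - references
    else:
        reference = reference_mean(expr, labels, mode)
        deltas = tumor_values - reference[:, None]

    sq = deltas**2
    scores = np.sqrt(
        np.sum((sq - sq.mean(axis=0, keepdims=True)) ** 2, axis=0) / (expr.m - 1)
    )
    return pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "depth_score": scores,
            "reference_mode": mode,
            "m_used": expr.m,
        }
    )
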