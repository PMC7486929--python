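"""Cohort-level summaries of a DEPTH-score distribution.

Two summaries: the Shannon diversity index of the score histogram
(intertumor heterogeneity of a cohort) and a coarse clone-number inference
(rounded ratio of each score to the cohort minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SdiResult", "CloneTable", "shannon_diversity", "clone_numbers", "round_half_up"]


@dataclass
class SdiResult:
    """Shannon diversity of scores binned into fixed half-open intervals."""

    n_intervals: int
    bin_edges: np.ndarray  # length n_intervals + 1
    proportions: np.ndarray  # length n_intervals, sums to 1
    sdi: float  # bits
    n_samples: int
    n_clamped: int  # scores outside [first edge, last edge) folded into end bins


@dataclass
class CloneTable:
    """Per-sample clone numbers and the minimum score they were scaled by."""

    table: pd.DataFrame  # columns: sample_id, clone_number
    min_score_used: float


def shannon_diversity(
    scores,
    n_intervals: int = 22,
    origin: float = 1.0,
    width: float = 1.0,
) -> SdiResult:
    """Shannon diversity index (bits) of scores over fixed half-open bins.

    Bin i (i = 1..n) is [origin + (i-1)*width, origin + i*width); with the
    defaults the bins are [1,2), [2,3), ..., [22,23). Scores below the first
    edge are counted in the first bin and scores at or above the last edge
    in the last bin; the number of such out-of-range scores is reported as
    ``n_clamped``. SDI = -sum p_i log2 p_i with the 0*log 0 = 0 convention.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    if width <= 0:
        raise ValueError("interval width must be positive")

    edges = origin + width * np.arange(n_intervals + 1, dtype=float)
    idx = np.floor((scores - origin) / width).astype(int)
    n_clamped = int(np.sum((idx < 0) | (idx >= n_intervals)))
    idx = np.clip(idx, 0, n_intervals - 1)
    counts = np.bincount(idx, minlength=n_intervals).astype(float)
    p = counts / scores.size
    nz = p > 0
    sdi = float(-(p[nz] * np.log2(p[nz])).sum())
    return SdiResult(
        n_intervals=n_intervals,
        bin_edges=edges,
        proportions=p,
        sdi=sdi,
        n_samples=scores.size,
        n_clamped=n_clamped,
    )


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero's positive side."""
    return int(math.floor(x + 0.5))


def clone_numbers(score_table: pd.DataFrame) -> CloneTable:
    """Infer clone numbers as the rounded ratio of each score to the minimum.

    ``score_table`` is the output of :func:`depthscore.core.depth_scores`
    (needs columns ``sample_id`` and ``depth_score``). The sample attaining
    the minimum score gets clone number 1; ratios are rounded half-up, so
    every clone number is a positive integer. Multiplying all scores by a
    constant leaves the clone numbers unchanged.
    """
    if "depth_score" not in score_table or "sample_id" not in score_table:
        raise ValueError("score table needs sample_id and depth_score columns")
    scores = score_table["depth_score"].to_numpy(dtype=float)
    if scores.size == 0:
        raise ValueError("empty score table")
    min_score = float(scores.min())
    if min_score <= 0:
        raise ValueError(
            "minimum DEPTH score is not positive; exclude zero-score samples "
            "before inferring clone numbers (the ratio is undefined)"
        )
    clones = [round_half_up(s / min_score) for s in scores]
    table = pd.DataFrame(
        {"sample_id": score_table["sample_id"].to_numpy(), "clone_number": clones}
    )
    return CloneTable(table=table, min_score_used=min_score)
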