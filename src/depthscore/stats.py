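"""Spearman correlation, one-sided Mann-Whitney U, and Benjamini-Hochberg FDR.

Conventions: average ranks for ties throughout; small instances get exact
p-values (full permutation for Spearman at n < 10, full enumeration of
group assignments for the U test at n1*n2 < 20) and larger ones the usual
large-sample approximations (Student-t for Spearman, continuity- and
tie-corrected normal for the U test).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Literal

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "TestResult",
    "FdrVector",
    "spearman",
    "mann_whitney_one_sided",
    "bh_adjust",
]

SPEARMAN_EXACT_MAX_N = 9  # full permutation below this; t-approximation above
MWU_EXACT_MAX_PRODUCT = 20  # exact enumeration while n1*n2 < 20


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p_value: float
    alternative: Literal["greater", "less"]
    n1: int
    n2: int


@dataclass
class FdrVector:
    raw_p: np.ndarray
    adjusted_p: np.ndarray


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks. For n < 10 the p-value
    is exact (all n! permutations of one rank vector, two-sided tail on
    |rho|); otherwise it comes from the Student-t approximation
    t = rho * sqrt((n-2)/(1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rhos = pc @ rxc / np.sqrt((pc * pc).sum(axis=1) * (rxc @ rxc))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def _u_statistic(ranks: np.ndarray, idx_a, n1: int, n2: int) -> float:
    return float(ranks[list(idx_a)].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_one_sided(
    a, b, alternative: Literal["greater", "less"] = "greater"
) -> TestResult:
    """One-sided Mann-Whitney U test of two independent groups.

    The statistic is U for the first group (from the average-rank sum).
    While n1*n2 < 20 the p-value is exact: every assignment of the pooled
    observations to groups is enumerated (tie-aware, no continuity
    correction) and the tail P(U* >= U) (or <=) is reported. Otherwise the
    continuity- and tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1, n2)
    if n1 * n2 < MWU_EXACT_MAX_PRODUCT:
        us = np.array(
            [
                _u_statistic(ranks, idx, n1, n2)
                for idx in combinations(range(n1 + n2), n1)
            ]
        )
        if alternative == "greater":
            p = float(np.mean(us >= u_obs - 1e-12))
        else:
            p = float(np.mean(us <= u_obs + 1e-12))
    else:
        res = sps.mannwhitneyu(
            a, b, alternative=alternative, use_continuity=True, method="asymptotic"
        )
        p = float(res.pvalue)
    return TestResult(
        statistic=u_obs, p_value=min(p, 1.0), alternative=alternative, n1=n1, n2=n2
    )


def bh_adjust(p) -> FdrVector:
    """Benjamini-Hochberg step-up FDR adjustment, in the original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return FdrVector(raw_p=p, adjusted_p=adjusted)
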