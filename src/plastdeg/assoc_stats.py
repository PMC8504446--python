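"""Rank statistics for the size/GC comparisons: Spearman and Mann-Whitney U.

Thin, contract-enforcing wrappers over scipy.stats. The U statistic is
reported for the FIRST sample (the R ``wilcox.test`` W convention), with an
exact p-value when both samples are small and tie-free and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: combined-size limit below which tie-free samples get an exact p-value
EXACT_LIMIT = 20


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    has_ties: bool


@dataclass(frozen=True)
class UTestResult:
    u: float
    p_value: float
    method: str  # 'exact' | 'normal-approx-tie-corrected'
    n1: int
    n2: int


def rank_average(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing the average rank of their span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty list")
    return stats.rankdata(arr, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("undefined correlation: zero rank variance")
    res = stats.spearmanr(x, y)
    ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    return CorrelationResult(
        rho=float(res.statistic), p_value=float(res.pvalue), n=int(x.size), has_ties=ties
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sample Mann-Whitney U (Wilcoxon rank-sum), two-sided.

    U = #{(i, j): x_i > y_j} + 0.5 #{x_i = y_j}, computed from average
    ranks. Exact enumeration p when n1 + n2 <= 20 with no ties, else
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rank_average(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        method = "exact"
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    else:
        method = "normal-approx-tie-corrected"
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return UTestResult(u=u1, p_value=p, method=method, n1=n1, n2=n2)
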