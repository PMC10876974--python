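"""Statistical primitives shared across the pipeline reports.

Thin, contract-checked wrappers around scipy: two-sided Fisher exact
(small-p-values definition), Pearson chi-squared without continuity
correction, Mann–Whitney U with star annotation, product-moment correlation,
and exact (Clopper–Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "StarCategory",
    "StarAnnotation",
    "DEFAULT_STAR_THRESHOLDS",
    "star_annotation",
    "mann_whitney_star",
    "fisher_exact_2x2",
    "chi_squared_rxc",
    "pearson_r",
    "binomial_ci",
]

# Significance thresholds used for star annotations on group comparisons
# (Bonferroni-style scaling of 0.05 / 0.01 / 0.001).
DEFAULT_STAR_THRESHOLDS: tuple[float, float, float] = (1.19e-3, 2.38e-4, 2.38e-5)


class StarCategory(str, enum.Enum):
    NS = "ns"
    ONE = "*"
    TWO = "**"
    THREE = "***"


@dataclass(frozen=True)
class StarAnnotation:
    p_value: float
    category: StarCategory
    thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS


def star_annotation(
    p: float, thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS
) -> StarAnnotation:
    """Categorize a p value by strict comparison to the three thresholds."""
    t1, t2, t3 = thresholds
    if not t1 > t2 > t3:
        raise ValueError("thresholds must be strictly decreasing")
    if p < t3:
        cat = StarCategory.THREE
    elif p < t2:
        cat = StarCategory.TWO
    elif p < t1:
        cat = StarCategory.ONE
    else:
        cat = StarCategory.NS
    return StarAnnotation(p_value=p, category=cat, thresholds=thresholds)


def mann_whitney_star(
    x: Sequence[float],
    y: Sequence[float],
    thresholds: tuple[float, float, float] = DEFAULT_STAR_THRESHOLDS,
) -> StarAnnotation:
    """Two-sided Mann–Whitney U with star annotation.

    Exact enumeration for small groups (n <= 8 each, no ties); otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return star_annotation(float(res.pvalue), thresholds)


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the small-p-values definition: sum the
    hypergeometric probabilities of all tables (fixed margins) no more
    likely than the observed one.  A table with a zero margin carries no
    information; p = 1 by convention (warned).
    """
    t = _check_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {t.shape}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(_st.fisher_exact(t, alternative="two-sided").pvalue)


def chi_squared_rxc(table) -> tuple[float, int, float]:
    """Pearson chi-squared test (no continuity correction) on an r x c table.

    Returns (statistic, degrees of freedom, p).  Zero expected cells make
    the statistic undefined and raise.
    """
    t = _check_table(table)
    res = _st.chi2_contingency(t, correction=False)
    if (res.expected_freq == 0).any():
        raise ValueError("zero expected cell count; test undefined")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = _st.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) confidence interval for a binomial fraction."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(_st.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_st.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high
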