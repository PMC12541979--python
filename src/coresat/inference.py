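"""Rank-based hypothesis tests and multiplicity corrections.

All downstream stages delegate their group comparisons here: Kruskal-Wallis
omnibus tests, two-sided Mann-Whitney U pairwise tests, classical one-way
ANOVA (used for the CLR heatmap comparison), and Bonferroni /
Benjamini-Hochberg adjustments.  Tests are two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "mann_whitney_u",
    "one_way_anova",
    "bonferroni",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test (plus optional adjustment)."""

    statistic: float
    pvalue: float
    statistic_name: str
    group_sizes: tuple[int, ...]
    adjusted_pvalue: float | None = None
    adjustment: str | None = None
    note: str | None = None

    def with_adjustment(self, adjusted: float, method: str) -> "TestResult":
        return TestResult(
            self.statistic,
            self.pvalue,
            self.statistic_name,
            self.group_sizes,
            adjusted_pvalue=min(1.0, float(adjusted)),
            adjustment=method,
            note=self.note,
        )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups, with tie correction.

    P comes from the chi-square(g-1) upper tail.  If every value in every
    group is identical the test is degenerate and returns H = 0, P = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    sizes = tuple(len(g) for g in groups)
    if sum(sizes) < 3:
        raise ValueError("kruskal_wallis needs total n >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "H", sizes, note="all values identical")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), "H", sizes)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; U reported as min(U1, U2).

    The exact null distribution is enumerated when n1*n2 <= 400 and there
    are no ties across the pooled data; otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) * len(y) <= 400) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return TestResult(u, float(res.pvalue), "U", (len(x), len(y)),
                      note=f"method={method}")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Classical one-way ANOVA: F = MS_between / MS_within, F(g-1, n-g) tail.

    Degenerate inputs: all values identical gives F = 0, P = 1; zero
    within-group variance with unequal means gives F = inf, P = 0, flagged
    in ``note``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("one_way_anova needs >= 2 groups of >= 2 values")
    sizes = tuple(len(g) for g in groups)
    n = sum(sizes)
    g = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(gr) * (gr.mean() - grand) ** 2 for gr in groups)
    ss_within = sum(((gr - gr.mean()) ** 2).sum() for gr in groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return TestResult(0.0, 1.0, "F", sizes, note="all values identical")
        return TestResult(np.inf, 0.0, "F", sizes,
                          note="zero within-group variance with unequal means")
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    p = float(stats.f.sf(f, g - 1, n - g))
    return TestResult(float(f), p, "F", sizes)


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, m * p); m defaults to len(pvalues)."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted p values.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out
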