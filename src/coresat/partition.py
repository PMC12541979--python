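"""Core/satellite partitioning from distribution-abundance relationships.

For each study group, every taxon is summarised by its distribution (the
percentage of the group's samples it occupies) and its mean percent
abundance across the samples where it is present.  An ordinary
least-squares regression of log10 mean abundance on distribution documents
the positive occupancy-abundance coupling; taxa at or above a prevalence
threshold (default 75 %) are labelled core and the rest satellite; the core
set's mean abundances are tested for log-normality by an equal-probability
chi-squared goodness-of-fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, to_relative_abundance

__all__ = [
    "RegressionFit",
    "GofResult",
    "Partition",
    "summarize_taxa",
    "fit_distribution_abundance",
    "partition_taxa",
    "partition_all_groups",
    "lognormal_gof",
    "partition_abundance_share",
]


@dataclass
class RegressionFit:
    """OLS fit of log10 mean abundance on distribution (%)."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    pvalue: float
    n_taxa: int
    log_abundance: bool


@dataclass
class GofResult:
    """Chi-squared goodness-of-fit of log10 abundances to a normal law."""

    chi2: float
    df: int
    pvalue: float
    n: int
    n_bins: int
    reliable: bool


@dataclass
class Partition:
    """Core/satellite labels for one group, with supporting evidence."""

    group: str
    labels: pd.Series  # taxon -> "core" | "satellite"
    threshold: float
    regression: RegressionFit | None
    gof: GofResult | None

    @property
    def core_taxa(self) -> list[str]:
        return list(self.labels.index[self.labels == "core"])

    @property
    def satellite_taxa(self) -> list[str]:
        return list(self.labels.index[self.labels == "satellite"])

    def counts(self) -> dict[str, int]:
        return {"core": len(self.core_taxa), "satellite": len(self.satellite_taxa)}


def summarize_taxa(m: CountMatrix, group: str) -> pd.DataFrame:
    """Per-taxon distribution and mean abundance within one group.

    Returns a DataFrame indexed by taxon with columns ``distribution``
    (percent of the group's samples where count > 0), ``mean_abundance``
    (mean percent relative abundance over those positive samples) and
    ``n_present``.  Taxa absent from every sample of the group are excluded.
    """
    samples = m.samples_in_group(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    counts = m.counts[samples]
    rel = to_relative_abundance(counts)
    present = counts > 0
    n_present = present.sum(axis=1)
    keep = n_present > 0
    d = 100.0 * n_present[keep] / len(samples)
    mean_ab = rel.where(present)[keep].mean(axis=1)
    out = pd.DataFrame(
        {"distribution": d, "mean_abundance": mean_ab, "n_present": n_present[keep]}
    )
    out.index.name = "taxon_id"
    return out


def fit_distribution_abundance(
    summary: pd.DataFrame, log_abundance: bool = True
) -> RegressionFit:
    """OLS regression of (log10) mean abundance on distribution.

    F = (R^2 / 1) / ((1 - R^2) / (n - 2)) with P from the F(1, n-2) upper
    tail; a perfectly collinear cloud gives R^2 = 1 and P = 0.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 taxa to fit the regression")
    x = summary["distribution"].to_numpy(dtype=float)
    y = summary["mean_abundance"].to_numpy(dtype=float)
    if log_abundance:
        y = np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in distribution; slope undefined")
    n = len(x)
    if np.ptp(y) == 0:
        # constant abundance: slope 0, no explained variance
        return RegressionFit(0.0, float(y[0]), 0.0, 0.0, (1, n - 2), 1.0,
                             n, log_abundance)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if 1.0 - r2 < 1e-15:
        f = math.inf
        p = 0.0
    else:
        f = (r2 / 1.0) / ((1.0 - r2) / (n - 2))
        p = float(stats.f.sf(f, 1, n - 2))
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_statistic=float(f),
        df=(1, n - 2),
        pvalue=p,
        n_taxa=n,
        log_abundance=log_abundance,
    )


def partition_taxa(
    summary: pd.DataFrame,
    threshold: float = 75.0,
    group: str = "",
    log_abundance: bool = True,
) -> Partition:
    """Label each taxon core (distribution >= threshold, inclusive) or satellite.

    The returned :class:`Partition` carries the distribution-abundance
    regression and the log-normal goodness-of-fit of the core set's mean
    abundances as evidence for the threshold choice.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must lie in (0, 100]")
    labels = pd.Series(
        np.where(summary["distribution"] >= threshold, "core", "satellite"),
        index=summary.index,
        name="label",
    )
    try:
        reg = (
            fit_distribution_abundance(summary, log_abundance=log_abundance)
            if len(summary) >= 3
            else None
        )
    except ValueError:
        reg = None  # e.g. every taxon fully prevalent: slope undefined
    core_ab = summary.loc[labels == "core", "mean_abundance"].to_numpy()
    gof = lognormal_gof(core_ab) if len(core_ab) >= 4 else None
    return Partition(group=group, labels=labels, threshold=threshold,
                     regression=reg, gof=gof)


def partition_all_groups(
    m: CountMatrix, threshold: float = 75.0, log_abundance: bool = True
) -> dict[str, Partition]:
    """Partition every group of the cohort at the same threshold."""
    return {
        g: partition_taxa(summarize_taxa(m, g), threshold, group=g,
                          log_abundance=log_abundance)
        for g in m.group_labels()
    }


def lognormal_gof(abundances: np.ndarray | list[float]) -> GofResult:
    """Chi-squared goodness-of-fit of abundances to a log-normal law.

    log10 abundances are fit by their sample mean and SD; observations are
    binned into k = max(4, ceil(sqrt(n))) equal-probability bins under the
    fitted normal, adjacent bins are merged until every expected count is
    >= 1, and chi2 = sum (obs - exp)^2 / exp with df = bins - 3 (two
    estimated parameters), floored at 1.  Fewer than 8 observations flags
    the result unreliable rather than raising.
    """
    x = np.log10(np.asarray(abundances, dtype=float))
    n = len(x)
    if n < 4:
        return GofResult(math.nan, 0, math.nan, n, 0, reliable=False)
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return GofResult(math.nan, 0, math.nan, n, 0, reliable=False)
    k = max(4, math.ceil(math.sqrt(n)))
    edges = stats.norm.ppf(np.arange(1, k) / k, loc=mu, scale=sd)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = np.full(k, n / k)
    # merge each undersized bin (expected < 1) into its right neighbour;
    # equal-probability bins make this a no-op whenever n >= k
    obs_list, exp_list = list(observed), list(expected)
    while len(exp_list) > 1 and min(exp_list) < 1.0:
        i = int(np.argmin(exp_list))
        j = i + 1 if i + 1 < len(exp_list) else i - 1
        e, o = exp_list.pop(i), obs_list.pop(i)
        j = j if j < i else j - 1
        exp_list[j] += e
        obs_list[j] += o
    obs = np.asarray(obs_list, dtype=float)
    exp = np.asarray(exp_list, dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = max(1, len(exp) - 3)
    p = float(stats.chi2.sf(chi2, df))
    return GofResult(chi2, df, p, n, len(exp), reliable=(n >= 8))


def partition_abundance_share(
    m: CountMatrix, partition: Partition, group: str
) -> pd.DataFrame:
    """Percent of each sample's reads carried by core vs satellite taxa.

    Returns per-sample rows with columns ``core`` and ``satellite`` (summing
    to 100) plus a ``mean`` row; this is the quantity behind statements like
    "core taxa constituted X % of total abundance".
    """
    samples = m.samples_in_group(group)
    counts = m.counts[samples]
    core = [t for t in partition.core_taxa if t in counts.index]
    totals = counts.sum(axis=0).astype(float)
    core_share = 100.0 * counts.loc[core].sum(axis=0) / totals
    out = pd.DataFrame({"core": core_share, "satellite": 100.0 - core_share})
    out.loc["mean"] = out.mean(axis=0)
    return out
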