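"""Alpha diversity: Fisher's log-series alpha, rarefaction, Shannon index.

Fisher's alpha is the diversity parameter of the log-series model, defined
implicitly by S = alpha * ln(1 + N/alpha) for S observed taxa among N
reads; it is computed on unrarefied counts.  The Shannon index (natural-log
units) is computed on counts rarefied without replacement to a common
depth, mirroring the vegan ``rrarefy``/``diversity`` convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .inference import TestResult, bonferroni, kruskal_wallis, mann_whitney_u
from .io import CountMatrix
from .partition import Partition

__all__ = ["fishers_alpha", "rarefy", "shannon", "diversity_by_group",
           "GroupDiversity"]

logger = logging.getLogger(__name__)


def fishers_alpha(S: int, N: int) -> float:
    """Solve S = alpha * ln(1 + N/alpha) for alpha by bracketed root search.

    Requires 0 < S < N (the log-series is undefined in the all-singleton
    limit S = N).  The returned alpha satisfies the defining equation to an
    absolute residual below 1e-8.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    if S >= N:
        raise ValueError("Fisher's alpha requires S < N (log-series limit)")

    def f(alpha: float) -> float:
        return alpha * np.log1p(N / alpha) - S

    alpha = optimize.brentq(f, 1e-10, 1e10, xtol=1e-12, rtol=8.9e-16)
    assert abs(f(alpha)) < 1e-8
    return float(alpha)


def rarefy(m: CountMatrix, depth: int | None = None, seed: int = 0) -> CountMatrix:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    ``depth`` defaults to the minimum sample total.  Sampling is
    multivariate hypergeometric per sample (the rrarefy model) and
    deterministic for a fixed seed; rarefied counts never exceed the
    originals and every rarefied column sums to ``depth`` exactly.
    """
    totals = m.sample_totals
    if depth is None:
        depth = int(totals.min())
    too_small = totals[totals < depth]
    if len(too_small):
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) {list(too_small.index)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sid in m.sample_ids:
        col = m.counts[sid].to_numpy()
        out[sid] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=m.counts.index)
    rarefied.index.name = m.counts.index.name
    return CountMatrix(rarefied, m.groups)


def shannon(abundances: Sequence[float]) -> float:
    """Shannon index H' = -sum p_i ln p_i over positive entries (nats)."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("abundance vector is all zero")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class GroupDiversity:
    """Per-sample diversity values plus the across-group tests."""

    values: pd.DataFrame  # sample, group, stratum, S, N, value
    omnibus: dict[str, TestResult]  # stratum -> Kruskal-Wallis
    pairwise: dict[str, pd.DataFrame]  # stratum -> MWU table (Bonferroni)


def _stratum_matrices(
    m: CountMatrix, partitions: Mapping[str, Partition] | None
) -> dict[str, CountMatrix]:
    strata = {"whole": m}
    if partitions is not None:
        for label in ("core", "satellite"):
            cols = {}
            for sid in m.sample_ids:
                part = partitions[m.groups[sid]]
                taxa = [t for t in (part.core_taxa if label == "core"
                                    else part.satellite_taxa)
                        if t in m.counts.index]
                col = pd.Series(0, index=m.counts.index)
                col.loc[taxa] = m.counts.loc[taxa, sid]
                cols[sid] = col
            sub = pd.DataFrame(cols)
            strata[label] = CountMatrix(sub, m.groups)
    return strata


def diversity_by_group(
    m: CountMatrix,
    partitions: Mapping[str, Partition] | None = None,
    metric: str = "fisher",
    depth: int | None = None,
    seed: int = 0,
) -> GroupDiversity:
    """Compute a diversity metric per sample and test it across groups.

    The metric is evaluated on the whole community and, when partitions are
    supplied, on each sample's core-only and satellite-only submatrix (a
    sample's own group's partition decides which taxa count as core for it).
    Fisher's alpha uses raw counts; Shannon uses counts rarefied to
    ``depth`` first.  A Kruskal-Wallis omnibus test and Bonferroni-adjusted
    pairwise Mann-Whitney U tests are attached per stratum; samples where
    the metric is undefined (e.g. S >= N for Fisher's alpha) are excluded
    from that stratum's test and logged.
    """
    if metric not in ("fisher", "shannon"):
        raise ValueError(f"unknown metric: {metric!r}")
    base = rarefy(m, depth=depth, seed=seed) if metric == "shannon" else m
    strata = _stratum_matrices(base, partitions)
    rows = []
    for label, sub in strata.items():
        for sid in sub.sample_ids:
            col = sub.counts[sid].to_numpy()
            S = int((col > 0).sum())
            N = int(col.sum())
            if N == 0:
                logger.info("sample %s has no reads in stratum %s; excluded",
                            sid, label)
                continue
            if metric == "fisher":
                if S >= N or S == 0:
                    logger.info(
                        "Fisher's alpha undefined for sample %s in stratum %s "
                        "(S=%d, N=%d); excluded", sid, label, S, N)
                    continue
                value = fishers_alpha(S, N)
            else:
                value = shannon(col)
            rows.append((sid, m.groups[sid], label, S, N, value))
    values = pd.DataFrame(
        rows, columns=["sample_id", "group", "stratum", "S", "N", "value"]
    )
    omnibus: dict[str, TestResult] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    group_names = m.group_labels()
    for label in strata:
        sub = values[values["stratum"] == label]
        by_group = [sub.loc[sub["group"] == g, "value"].to_numpy()
                    for g in group_names]
        by_group = [g for g in by_group if len(g) > 0]
        if len(by_group) >= 2:
            omnibus[label] = kruskal_wallis(by_group)
        pairs = []
        present = [g for g in group_names
                   if (sub["group"] == g).sum() > 0]
        n_pairs = len(present) * (len(present) - 1) // 2
        for i, ga in enumerate(present):
            for gb in present[i + 1:]:
                res = mann_whitney_u(
                    sub.loc[sub["group"] == ga, "value"],
                    sub.loc[sub["group"] == gb, "value"],
                )
                res = res.with_adjustment(res.pvalue * n_pairs, "bonferroni")
                pairs.append((ga, gb, res.statistic, res.pvalue,
                              res.adjusted_pvalue))
        pairwise[label] = pd.DataFrame(
            pairs, columns=["group_a", "group_b", "U", "pvalue", "adjusted_pvalue"]
        )
    return GroupDiversity(values, omnibus, pairwise)
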