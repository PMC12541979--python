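"""Predicted-function profiles: pathway aggregation, stratification, CLR tests.

Consumes the stratified contribution tables emitted by metagenome
prediction tools (long-form sample/taxon/function/abundance records),
aggregates function abundances to level-3 pathways, restricts them to the
core or satellite subcommunity of a partition, filters to pathways holding
more than 1 % of total predicted functionality, applies the centred
log-ratio transform, and runs the group comparisons (Kruskal-Wallis + BH,
pairwise Mann-Whitney U + Bonferroni, or ANOVA on CLR values).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta import AnosimResult, PcoaResult, anosim, bray_curtis, pcoa
from .inference import (benjamini_hochberg, bonferroni, kruskal_wallis,
                        mann_whitney_u, one_way_anova)

__all__ = [
    "aggregate_to_pathways",
    "stratify_by_partition",
    "abundant_pathways",
    "satellite_exclusive_pathways",
    "clr_transform",
    "compare_pathways",
    "pathway_pcoa",
]

logger = logging.getLogger(__name__)


def _normalize_pct(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero functional total: {list(zero.index)}")
    return 100.0 * table / totals


def aggregate_to_pathways(
    contrib: pd.DataFrame,
    mapping: pd.DataFrame | Mapping[str, Sequence[str]] | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Sum function abundances into pathways, per sample.

    ``mapping`` maps function_id -> pathway id(s) (a DataFrame with
    ``function_id``/``pathway_id`` columns, or a dict of lists); a function
    belonging to k pathways contributes its full abundance to each (the
    standard hierarchy-collapse convention).  With ``mapping=None`` the
    function_id namespace is taken to be pathways already.  Unmapped
    functions are excluded and their count logged (also stored in
    ``.attrs['n_unmapped_functions']``).  Columns are normalized to percent
    unless ``normalize=False``.
    """
    df = contrib
    n_unmapped = 0
    if mapping is not None:
        if isinstance(mapping, pd.DataFrame):
            if not {"function_id", "pathway_id"} <= set(mapping.columns):
                raise ValueError("mapping needs function_id and pathway_id columns")
            map_df = mapping[["function_id", "pathway_id"]]
        else:
            if len(mapping) == 0:
                raise ValueError("empty function-to-pathway mapping")
            map_df = pd.DataFrame(
                [(f, p) for f, ps in mapping.items() for p in ps],
                columns=["function_id", "pathway_id"],
            )
        if len(map_df) == 0:
            raise ValueError("empty function-to-pathway mapping")
        unmapped = set(df["function_id"]) - set(map_df["function_id"])
        n_unmapped = len(unmapped)
        if n_unmapped:
            logger.info("%d function id(s) had no pathway mapping; excluded",
                        n_unmapped)
        mapped = df.merge(map_df, on="function_id", how="inner")
        df = mapped.drop(columns=["function_id"]).rename(
            columns={"pathway_id": "function_id"})
    table = (
        df.groupby(["function_id", "sample_id"])["abundance"]
        .sum()
        .unstack(fill_value=0.0)
    )
    table.index.name = "pathway_id"
    if normalize:
        table = _normalize_pct(table)
    table.attrs["n_unmapped_functions"] = n_unmapped
    return table


def stratify_by_partition(
    contrib: pd.DataFrame,
    labels: pd.Series,
    stratum: str,
    mapping: pd.DataFrame | Mapping[str, Sequence[str]] | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Aggregate contributions restricted to taxa of one partition stratum.

    ``labels`` maps taxon_id -> {"core", "satellite"}; ``stratum`` selects
    which taxa contribute ("whole" keeps all).  Samples whose restricted
    total is zero are flagged, logged, and excluded from the normalized
    table (they carry no information for that stratum's tests).
    """
    if stratum not in ("whole", "core", "satellite"):
        raise ValueError(f"unknown stratum: {stratum!r}")
    missing = set(contrib["taxon_id"]) - set(labels.index)
    if stratum != "whole" and missing:
        raise ValueError(f"taxa missing from partition labels: {sorted(missing)[:5]}")
    sub = contrib
    if stratum != "whole":
        keep_taxa = set(labels.index[labels == stratum])
        sub = contrib[contrib["taxon_id"].isin(keep_taxa)]
    table = aggregate_to_pathways(sub, mapping=mapping, normalize=False)
    table = table.reindex(columns=sorted(set(contrib["sample_id"])), fill_value=0.0)
    totals = table.sum(axis=0)
    empty = list(totals.index[totals <= 0])
    if empty:
        logger.info("sample(s) with zero %s-stratum functional abundance "
                    "excluded: %s", stratum, empty)
        table = table.drop(columns=empty)
    if normalize:
        table = _normalize_pct(table)
    table.attrs["excluded_samples"] = empty
    return table


def abundant_pathways(table: pd.DataFrame, threshold_pct: float = 1.0) -> pd.DataFrame:
    """Keep pathways holding strictly more than ``threshold_pct`` of the grand total."""
    share = 100.0 * table.sum(axis=1) / table.to_numpy().sum()
    return table.loc[share > threshold_pct]


def satellite_exclusive_pathways(
    core: pd.DataFrame, satellite: pd.DataFrame
) -> list[str]:
    """Pathways present in the satellite stratum but absent everywhere in core.

    A pathway qualifies if it has positive abundance in at least one sample
    of the satellite table and zero abundance in every sample of the core
    table (absence from the core table counts as zero).
    """
    sat_present = set(satellite.index[(satellite > 0).any(axis=1)])
    core_present = set(core.index[(core > 0).any(axis=1)])
    return sorted(sat_present - core_present)


def clr_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform with multiplicative zero replacement.

    Zeros are replaced per sample by a pseudocount equal to half the
    smallest positive value in the whole table, with the sample's positive
    entries scaled down so its total is preserved (multiplicative
    replacement); then clr(x)_i = ln x_i - mean(ln x), so every sample's
    CLR values sum to zero.
    """
    X = table.to_numpy(dtype=float).copy()
    if (X < 0).any():
        raise ValueError("table must be non-negative")
    col_tot = X.sum(axis=0)
    if (col_tot <= 0).any():
        bad = list(table.columns[col_tot <= 0])
        raise ValueError(f"sample(s) entirely zero: {bad}")
    pos = X[X > 0]
    delta = 0.5 * pos.min()
    for j in range(X.shape[1]):
        col = X[:, j]
        zeros = col == 0
        if zeros.any():
            k = int(zeros.sum())
            scale = (col_tot[j] - k * delta) / col_tot[j]
            if scale <= 0:
                raise ValueError("pseudocount exceeds sample total; table too sparse")
            col[~zeros] *= scale
            col[zeros] = delta
    logx = np.log(X)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.index, columns=table.columns)


def compare_pathways(
    values: pd.DataFrame,
    groups: pd.Series,
    test: str = "kw",
) -> pd.DataFrame:
    """Per-pathway group comparison with the stage's multiplicity corrections.

    ``values`` is pathway x sample (CLR values or relative abundances).
    The omnibus test per pathway is Kruskal-Wallis (``test="kw"``) or
    one-way ANOVA (``test="anova"``), BH-adjusted across pathways; pairwise
    Mann-Whitney U P values are Bonferroni-adjusted by the number of group
    pairs.  Pathways constant across all samples are skipped and logged.
    Rows are sorted by adjusted omnibus P.
    """
    if test not in ("kw", "anova"):
        raise ValueError(f"unknown test: {test!r}")
    lab = groups.reindex(values.columns)
    names = list(dict.fromkeys(lab))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for pid, row in values.iterrows():
        arr = row.to_numpy(dtype=float)
        if np.ptp(arr) == 0:
            logger.info("pathway %s constant across samples; test skipped", pid)
            continue
        by_group = [arr[(lab == g).to_numpy()] for g in names]
        res = kruskal_wallis(by_group) if test == "kw" else one_way_anova(by_group)
        rec = {"pathway_id": pid, "statistic": res.statistic, "pvalue": res.pvalue}
        for ga, gb in pairs:
            mwu = mann_whitney_u(arr[(lab == ga).to_numpy()],
                                 arr[(lab == gb).to_numpy()])
            rec[f"p_{ga}_vs_{gb}"] = mwu.pvalue
            rec[f"p_adj_{ga}_vs_{gb}"] = min(1.0, mwu.pvalue * len(pairs))
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_pvalue"] = benjamini_hochberg(out["pvalue"].to_numpy())
        out = out.sort_values("adjusted_pvalue", kind="stable").set_index("pathway_id")
    out.attrs["test"] = test
    return out


def pathway_pcoa(
    table: pd.DataFrame,
    groups: pd.Series | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[PcoaResult, AnosimResult | None]:
    """PCoA of Bray-Curtis distances between samples' pathway profiles.

    Composes :func:`coresat.beta.bray_curtis` and :func:`coresat.beta.pcoa`
    on the pathway relative-abundance table; when group labels are given,
    ANOSIM on the same distance matrix is returned alongside.
    """
    D = bray_curtis(table)
    res = pcoa(D)
    test = anosim(D, groups, n_perm=n_perm, seed=seed) if groups is not None else None
    return res, test
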