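"""Tabular I/O and preprocessing for taxon-by-sample count data.

The pipeline's universal substrate is the :class:`CountMatrix`: an integer
taxon x sample table plus a group label per sample.  Readers accept the
plain-text dialects common in amplicon workflows (TSV count tables, CSV
metadata, 7-rank taxonomy TSV, and the stratified/unstratified layouts
emitted by metagenome-prediction tools); preprocessing implements the two
upstream filtering rules applied before any statistics: dataset-wide
singleton removal and collapsing of exact-sequence variants that share a
species-level assignment into one species OTU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "RANKS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxonomy_table",
    "read_contribution_table",
    "read_function_table",
    "remove_singleton_taxa",
    "collapse_to_species_otus",
    "to_relative_abundance",
]

#: The seven canonical taxonomic ranks, in order.
RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer taxon x sample count table with per-sample group labels.

    Invariants enforced on construction: unique taxon and sample ids, no
    negative counts, a group label for every sample, and no all-zero taxon
    rows (absent taxa are dropped, so every retained taxon has at least one
    positive entry).
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        _check_unique(counts.index, "taxon")
        _check_unique(counts.columns, "sample")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))
                r, c = bad[0]
                raise ValueError(
                    f"non-integer count at taxon {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}"
                )
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        keep = counts.sum(axis=1) > 0
        counts = counts.loc[keep]
        missing = [s for s in counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        object.__setattr__(self, "groups", self.groups.reindex(counts.columns))

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.groups))

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise ValueError(f"unknown group label: {group!r}")
        return [s for s in self.counts.columns if self.groups[s] == group]

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[samples].copy(), self.groups.loc[samples])

    def subset_taxa(self, taxa: Iterable[str]) -> "CountMatrix":
        taxa = [t for t in taxa if t in self.counts.index]
        return CountMatrix(self.counts.loc[taxa].copy(), self.groups)


def read_count_table(path: str | Path, orientation: str = "taxa_by_samples") -> pd.DataFrame:
    """Read a TSV count table into a taxon x sample integer DataFrame.

    ``orientation`` declares the file layout: ``"taxa_by_samples"`` (rows are
    taxa; the amplicon convention and default) or ``"samples_by_taxa"``
    (rows are samples; transposed on read).  Duplicate ids and non-integer
    counts are hard errors.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if orientation == "samples_by_taxa":
        df = df.T
    _check_unique(df.index, "taxon")
    _check_unique(df.columns, "sample")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=np.int64)
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except ValueError as exc:
            raise ValueError(f"non-numeric count in sample column {col!r}: {exc}") from exc
        if not np.allclose(vals, np.round(vals)):
            bad = df.index[vals != np.round(vals)][0]
            raise ValueError(f"non-integer count at taxon {bad!r}, sample {col!r}")
        out[col] = vals.astype(np.int64).to_numpy()
    return out


def write_count_table(counts: pd.DataFrame | CountMatrix, path: str | Path) -> None:
    """Write a taxon x sample count table as TSV (header cell ``taxon_id``)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    df = df.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata CSV; requires ``sample_id`` and ``group`` columns.

    Returns a DataFrame indexed by sample_id; extra columns are clinical
    covariates passed through untouched.
    """
    df = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing mandatory column {col!r}")
    _check_unique(df["sample_id"], "sample")
    return df.set_index("sample_id")


def read_taxonomy_table(path: str | Path) -> pd.DataFrame:
    """Read a 7-rank taxonomy TSV (taxon_id + domain..species columns).

    Unassigned ranks may be empty or NA; they are normalized to ``None``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table is missing rank columns: {missing}")
    df = df[RANKS].where(df[RANKS].notna() & (df[RANKS] != ""), None)
    return df


def read_contribution_table(path: str | Path) -> pd.DataFrame:
    """Read a stratified (long-form) function contribution TSV.

    Expected columns: ``sample_id``, ``taxon_id``, ``function_id``,
    ``abundance``.  (sample, taxon, function) must be unique and abundances
    non-negative.
    """
    df = pd.read_csv(path, sep="\t")
    need = ["sample_id", "taxon_id", "function_id", "abundance"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"contribution table is missing columns: {missing}")
    if (df["abundance"] < 0).any():
        raise ValueError("negative abundance in contribution table")
    if df.duplicated(subset=["sample_id", "taxon_id", "function_id"]).any():
        raise ValueError("duplicate (sample, taxon, function) record")
    return df[need].copy()


def read_function_table(path: str | Path) -> pd.DataFrame:
    """Read an unstratified function x sample TSV (first column function_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "function")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative abundance in function table")
    return df


def remove_singleton_taxa(m: CountMatrix) -> CountMatrix:
    """Drop taxa whose total count across the whole dataset equals 1.

    This is the dataset-wide singleton rule applied after denoising; taxa
    with total count >= 2 (even 1+1 across two samples) are retained and the
    sample set is unchanged.  Idempotent.
    """
    keep = m.counts.sum(axis=1) != 1
    return CountMatrix(m.counts.loc[keep].copy(), m.groups)


def collapse_to_species_otus(m: CountMatrix, taxonomy: pd.DataFrame) -> CountMatrix:
    """Merge rows sharing an identical species-level lineage into one OTU.

    Rows whose full 7-rank lineage (case-sensitive) is identical and has a
    species assignment are summed into one row keyed by the joined lineage;
    rows without a species-level assignment pass through unmerged under
    their original id.  Per-sample column totals are conserved exactly
    (integer arithmetic).
    """
    missing = [t for t in m.taxon_ids if t not in taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from taxonomy table: {missing[:5]}")
    lineage_key: dict[str, str] = {}
    for t in m.taxon_ids:
        row = taxonomy.loc[t, RANKS]
        if row["species"] is None or pd.isna(row["species"]):
            lineage_key[t] = t  # pass through unmerged
        else:
            lineage_key[t] = ";".join("" if pd.isna(v) or v is None else str(v) for v in row)
    keys = pd.Series({t: lineage_key[t] for t in m.taxon_ids})
    collapsed = m.counts.groupby(keys, sort=False).sum()
    collapsed.index.name = m.counts.index.name
    return CountMatrix(collapsed, m.groups)


def to_relative_abundance(m: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Convert counts to percent relative abundance (each column sums to 100)."""
    df = m.counts if isinstance(m, CountMatrix) else m
    totals = df.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    return 100.0 * df / totals
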