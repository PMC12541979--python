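"""Community structure: Bray-Curtis, ANOSIM, SIMPER, PCoA, ellipses.

Pairwise Bray-Curtis dissimilarities feed four analyses: intra/inter-group
similarity summaries, the rank-based ANOSIM permutation test (with
Bonferroni-adjusted pairwise runs), the SIMPER decomposition of average
between-group dissimilarity into additive per-taxon contributions, and
principal coordinates with 95 % confidence ellipses per group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import CountMatrix, to_relative_abundance

__all__ = [
    "DistanceMatrix",
    "AnosimResult",
    "PcoaResult",
    "EllipseParams",
    "bray_curtis",
    "group_similarity_summary",
    "anosim",
    "pairwise_anosim",
    "simper",
    "pcoa",
    "confidence_ellipse",
]


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarity matrix with sample labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.data.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(a)).max() > 0:
            raise ValueError("diagonal must be exactly zero")
        if a.min() < 0 or a.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis entries must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.data.to_numpy(), checks=False)

    def submatrix(self, samples: list[str]) -> "DistanceMatrix":
        return DistanceMatrix(self.data.loc[samples, samples])

    def similarity(self) -> pd.DataFrame:
        """1 - d, the similarity convention used for group summaries."""
        return 1.0 - self.data


@dataclass
class AnosimResult:
    r: float
    pvalue: float
    n_permutations: int
    method: str
    group_sizes: dict[str, int]
    adjusted_pvalue: float | None = None


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # dropped axes, reported not used


@dataclass
class EllipseParams:
    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    rotation_deg: float
    level: float
    degenerate: bool


def bray_curtis(data: CountMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(j,k) = sum|x_ij - x_ik| / sum(x_ij + x_ik).

    Accepts counts or relative abundances with samples as columns; the
    statistic is scale-free per sample pair only if abundances are on a
    common scale, so counts are converted to percent relative abundance
    first.
    """
    if isinstance(data, CountMatrix):
        X = to_relative_abundance(data)
    else:
        X = data
        zero = X.sum(axis=0) <= 0
        if zero.any():
            raise ValueError(
                f"sample(s) with zero total: {list(X.columns[zero])}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    d = pdist(X.to_numpy().T, metric="braycurtis")
    mat = pd.DataFrame(squareform(d), index=X.columns, columns=X.columns)
    np.fill_diagonal(mat.values, 0.0)
    return DistanceMatrix(mat)


def group_similarity_summary(D: DistanceMatrix, groups: pd.Series) -> pd.DataFrame:
    """Mean +/- SD Bray-Curtis similarity within and between groups.

    One row per group (intra-group pairs) and one per unordered group pair
    (inter-group pairs); SDs are taken over the same pair sets.
    """
    sim = D.similarity().to_numpy()
    ids = D.sample_ids
    lab = groups.reindex(ids).to_numpy()
    names = list(dict.fromkeys(lab))
    rows = []
    for g in names:
        idx = np.where(lab == g)[0]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        vals = [sim[i, j] for i, j in itertools.combinations(idx, 2)]
        rows.append(("intra", g, g, np.mean(vals), np.std(vals, ddof=0), len(vals)))
    for ga, gb in itertools.combinations(names, 2):
        ia = np.where(lab == ga)[0]
        ib = np.where(lab == gb)[0]
        vals = [sim[i, j] for i in ia for j in ib]
        rows.append(("inter", ga, gb, np.mean(vals), np.std(vals, ddof=0), len(vals)))
    return pd.DataFrame(
        rows, columns=["kind", "group_a", "group_b", "mean_similarity",
                       "sd_similarity", "n_pairs"]
    )


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    D: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> AnosimResult:
    """ANOSIM: R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).

    Ranks (mid-ranks for ties) are taken over all off-diagonal
    dissimilarities.  P is estimated by random relabeling of samples with
    the (1 + #{R_perm >= R_obs}) / (1 + n_perm) estimator, deterministic for
    a fixed seed; with ``exact=True`` every distinct assignment of the
    label multiset is enumerated instead and P is the exact proportion of
    assignments with R_perm >= R_obs.
    """
    ids = D.sample_ids
    lab = groups.reindex(ids).to_numpy()
    sizes = pd.Series(lab).value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError(f"group(s) of size 1: {list(sizes.index[sizes < 2])}")
    n = len(ids)
    cond = D.condensed()
    ranks = stats.rankdata(cond)  # mid-ranks for ties
    ii, jj = np.triu_indices(n, k=1)
    within = lab[ii] == lab[jj]
    r_obs = _anosim_r(ranks, within, n)

    if exact:
        if math.factorial(n) > 1_000_000:
            raise ValueError("exact enumeration is only feasible for small n")
        # enumerate distinct label assignments of the label multiset
        count_ge = 0
        total = 0
        from itertools import permutations

        seen: set[tuple] = set()
        for perm in permutations(lab):
            if perm in seen:
                continue
            seen.add(perm)
            pl = np.asarray(perm)
            w = pl[ii] == pl[jj]
            total += 1
            if _anosim_r(ranks, w, n) >= r_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        return AnosimResult(r_obs, p, total, "exact", sizes.to_dict())

    rng = np.random.default_rng(seed)
    count_ge = 0
    pl = lab.copy()
    for _ in range(n_perm):
        rng.shuffle(pl)
        w = pl[ii] == pl[jj]
        if _anosim_r(ranks, w, n) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return AnosimResult(r_obs, p, n_perm, "permutation", sizes.to_dict())


def pairwise_anosim(
    D: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict[tuple[str, str], AnosimResult]:
    """ANOSIM per group pair on the pair's submatrix, Bonferroni-adjusted.

    Adjusted P = min(1, P * n_pairs); never below the raw P.
    """
    ids = D.sample_ids
    lab = groups.reindex(ids)
    names = list(dict.fromkeys(lab))
    pairs = list(itertools.combinations(names, 2))
    out: dict[tuple[str, str], AnosimResult] = {}
    for k, (ga, gb) in enumerate(pairs):
        keep = [s for s in ids if lab[s] in (ga, gb)]
        res = anosim(D.submatrix(keep), lab.loc[keep], n_perm=n_perm,
                     seed=seed + k)
        res.adjusted_pvalue = min(1.0, res.pvalue * len(pairs))
        out[(ga, gb)] = res
    return out


def simper(
    abundances: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """SIMPER decomposition of average between-group Bray-Curtis dissimilarity.

    For every between-group sample pair (j, k) the per-taxon term is
    delta_i = |x_ij - x_ik| / sum_l (x_lj + x_lk); taxon contributions are
    the means over all pairs, so they sum exactly to the mean between-group
    dissimilarity.  Rows are sorted by contribution (descending) with
    percent and cumulative-percent columns plus mean abundance per group.
    ``abundances`` should be on the scale used for bray_curtis (percent
    relative abundance in this pipeline).
    """
    lab = groups.reindex(abundances.columns)
    a_cols = [s for s in abundances.columns if lab[s] == group_a]
    b_cols = [s for s in abundances.columns if lab[s] == group_b]
    if not a_cols or not b_cols:
        raise ValueError("both groups need at least one sample")
    X = abundances.to_numpy()
    ai = [abundances.columns.get_loc(c) for c in a_cols]
    bi = [abundances.columns.get_loc(c) for c in b_cols]
    contrib = np.zeros(X.shape[0])
    n_pairs = 0
    for j in ai:
        for k in bi:
            denom = (X[:, j] + X[:, k]).sum()
            contrib += np.abs(X[:, j] - X[:, k]) / denom
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    pct = 100.0 * contrib / total if total > 0 else np.zeros_like(contrib)
    out = pd.DataFrame(
        {
            "mean_contribution": contrib,
            "pct_contribution": pct,
            "mean_abundance_a": X[:, ai].mean(axis=1),
            "mean_abundance_b": X[:, bi].mean(axis=1),
        },
        index=abundances.index,
    )
    out = out.sort_values("mean_contribution", ascending=False)
    out["cumulative_pct"] = out["pct_contribution"].cumsum()
    out.attrs["overall_dissimilarity"] = float(total)
    out.attrs["groups"] = (group_a, group_b)
    return out


def pcoa(D: DistanceMatrix) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the double-centred Gram matrix.

    B = -1/2 J D^2 J with J the centring matrix; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues.
    Negative eigenvalues (non-Euclidean distances) are reported and their
    axes dropped; percent variance is relative to the positive-eigenvalue
    sum.
    """
    a = D.data.to_numpy()
    n = a.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (a**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * abs(vals).max()) if vals.size else 0.0
    pos = vals > tol
    lam = vals[pos]
    coords = vecs[:, pos] * np.sqrt(lam)
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=D.sample_ids, columns=axes),
        eigenvalues=lam,
        proportion_explained=lam / lam.sum() if lam.size else lam,
        negative_eigenvalues=vals[vals < -tol],
    )


def confidence_ellipse(
    coords: pd.DataFrame, level: float = 0.95
) -> EllipseParams:
    """Confidence ellipse of a 2-D point cloud from its covariance.

    Centre is the mean; semi-axes are sqrt(eigenvalue * chi2_2 quantile at
    ``level``) along the covariance eigenvectors.  A (near-)singular
    covariance is flagged degenerate (line or point) rather than raised.
    """
    X = coords.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("confidence_ellipse expects 2-D coordinates")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for an ellipse")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    degenerate = bool(vals[-1] <= 1e-12 * max(vals[0], 1.0))
    semi = np.sqrt(np.clip(vals, 0.0, None) * q)
    angle = math.degrees(math.atan2(vecs[1, 0], vecs[0, 0]))
    return EllipseParams(center, semi, angle, level, degenerate)
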