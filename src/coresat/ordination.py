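"""Constrained ordination: RDA, CCA, permutation pseudo-F, forward selection.

Explains community (or predicted-function) variation by clinical
covariates.  Redundancy analysis regresses a centred response matrix on
the covariates and decomposes the fitted variance; canonical
correspondence analysis does the analogue on chi-square-standardized
contingency residuals with row weights.  Each candidate covariate is
tested by a Monte-Carlo pseudo-F permutation test conditioning on the
already-selected covariates (reduced-model row permutation), and forward
selection adds the best candidate while its permutation P stays at or
below alpha.

Categorical covariates are dummy-coded with a first-level reference and a
multi-level factor is tested as a block (df = levels - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrdinationResult",
    "SelectionStep",
    "hellinger",
    "rda",
    "cca",
    "permutation_pseudo_f",
    "forward_select",
]


def hellinger(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of per-sample proportions (samples as columns).

    The standard pre-transform that makes species abundance data suitable
    for the Euclidean geometry of RDA.
    """
    totals = rel_abund.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("samples must have positive totals")
    return np.sqrt(rel_abund / totals)


def _design_blocks(X: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Dummy-code each covariate into a block (numeric: itself; factor: levels-1)."""
    blocks: dict[str, pd.DataFrame] = {}
    for col in X.columns:
        s = X[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks[col] = s.to_frame().astype(float)
        else:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks[col] = d
    return blocks


def _design_matrix(X: pd.DataFrame) -> np.ndarray:
    blocks = _design_blocks(X)
    if not blocks:
        return np.empty((len(X), 0))
    return np.concatenate([b.to_numpy() for b in blocks.values()], axis=1)


def _project_ss(Xc: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Fitted values of Y ~ Xc and the rank of Xc (columns assumed centred)."""
    if Xc.shape[1] == 0:
        return np.zeros_like(Y), 0
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    keep = diag > tol
    Q = Q[:, keep]
    return Q @ (Q.T @ Y), int(keep.sum())


@dataclass
class SelectionStep:
    variable: str
    added_inertia: float
    pseudo_f: float
    pvalue: float
    df_added: int
    cumulative_fraction: float


@dataclass
class OrdinationResult:
    method: str
    total_inertia: float
    constrained_inertia: float
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    rank_deficient_columns: list[str] = field(default_factory=list)
    selected: list[SelectionStep] = field(default_factory=list)
    #: per selection step: {candidate: (added_inertia,)} audit of what was tried
    trail: list[dict[str, float]] = field(default_factory=list)

    @property
    def explained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


def _prepare_rda(Y: pd.DataFrame) -> np.ndarray:
    Yc = Y.to_numpy(dtype=float)
    return Yc - Yc.mean(axis=0, keepdims=True)


def _prepare_cca(Y: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square standardized residuals and row weights of a contingency table."""
    A = Y.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("CCA requires a non-negative response matrix")
    if (A.sum(axis=1) <= 0).any() or (A.sum(axis=0) <= 0).any():
        raise ValueError("CCA requires positive row and column sums")
    total = A.sum()
    P = A / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    S = (P - E) / np.sqrt(E)
    return S, r


def _weighted_center(Xd: np.ndarray, w: np.ndarray) -> np.ndarray:
    mean = (w[:, None] * Xd).sum(axis=0) / w.sum()
    return Xd - mean


def _fit(method: str, Y: pd.DataFrame, Xd: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Return (response-in-analysis-space, design-in-analysis-space, total inertia, rank)."""
    if method == "rda":
        Z = _prepare_rda(Y)
        Xc = Xd - Xd.mean(axis=0, keepdims=True) if Xd.shape[1] else Xd
        total = float((Z**2).sum())
        return Z, Xc, total, Xc.shape[1]
    elif method == "cca":
        S, r = _prepare_cca(Y)
        Xc = _weighted_center(Xd, r) if Xd.shape[1] else Xd
        Xw = np.sqrt(r)[:, None] * Xc
        total = float((S**2).sum())
        return S, Xw, total, Xw.shape[1]
    raise ValueError(f"unknown method: {method!r}")


def _ordination(method: str, Y: pd.DataFrame, X: pd.DataFrame) -> OrdinationResult:
    n = len(X)
    Xd = _design_matrix(X)
    if n <= Xd.shape[1] + 1 and method == "rda":
        # saturated or over-parameterized designs are allowed but noted
        pass
    Z, Xc, total, _ = _fit(method, Y, Xd)
    fitted, rank = _project_ss(Xc, Z)
    constrained = float((fitted**2).sum())
    rank_deficient = []
    if rank < Xc.shape[1]:
        # identify columns dropped by the pivoted-rank projection
        names = []
        for col, block in _design_blocks(X).items():
            names.extend(block.columns)
        rank_deficient = [f"(design rank {rank} < {Xc.shape[1]} columns)"]
    # constrained axes: eigen-decomposition of the fitted covariance
    if fitted.size and constrained > 0:
        U, svals, _ = np.linalg.svd(fitted, full_matrices=False)
        eig = svals**2
        keep = eig > 1e-12 * eig.max()
        eig = eig[keep]
        scores = U[:, keep] * svals[keep]
    else:
        eig = np.array([])
        scores = np.zeros((len(Y.index), 0))
    axes = [f"{method.upper()}{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        method=method,
        total_inertia=total,
        constrained_inertia=constrained,
        eigenvalues=eig,
        site_scores=pd.DataFrame(scores, index=Y.index, columns=axes),
        rank_deficient_columns=rank_deficient,
    )


def rda(Y: pd.DataFrame, X: pd.DataFrame) -> OrdinationResult:
    """Redundancy analysis of response matrix Y (samples x responses) on X.

    Y is column-centred internally; categorical covariates are dummy-coded.
    Constrained inertia is the sum of squares of the fitted values, so the
    explained fraction equals 1 - RSS/TSS of the multivariate regression.
    Rank-deficient designs are fit on the reduced rank and flagged.
    """
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same number of samples (rows)")
    return _ordination("rda", Y, X)


def cca(Y: pd.DataFrame, X: pd.DataFrame) -> OrdinationResult:
    """Canonical correspondence analysis of non-negative Y on X.

    Y is converted to chi-square standardized residuals under row/column
    independence; the design is row-weighted by the sample masses, and
    inertia is in chi-square units (total inertia equals the contingency
    chi-square statistic divided by the grand total).
    """
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same number of samples (rows)")
    return _ordination("cca", Y, X)


def permutation_pseudo_f(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    selected: Sequence[str],
    candidate: str,
    method: str = "rda",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo pseudo-F test of adding ``candidate`` given ``selected``.

    pseudo-F = (added inertia / df_added) / (residual inertia / df_residual)
    where the added inertia is the gain in constrained inertia from the
    candidate block after conditioning on the selected covariates.  The
    null distribution permutes the rows of the reduced-model residuals
    (Freedman-Lane); P = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    deterministic per seed.
    """
    if candidate in selected:
        raise ValueError(f"candidate {candidate!r} is already selected")
    blocks = _design_blocks(X)
    sel_cols = [blocks[v].to_numpy() for v in selected]
    Xd_sel = (np.concatenate(sel_cols, axis=1) if sel_cols
              else np.empty((len(X), 0)))
    Xd_cand = blocks[candidate].to_numpy()
    Z, Xc_sel, total, _ = _fit(method, Y, Xd_sel)
    # candidate block in the same analysis space
    if method == "rda":
        Xc_cand = Xd_cand - Xd_cand.mean(axis=0, keepdims=True)
    else:
        _, r = _prepare_cca(Y)
        Xc_cand = np.sqrt(r)[:, None] * _weighted_center(Xd_cand, r)
    fitted_sel, rank_sel = _project_ss(Xc_sel, Z)
    resid = Z - fitted_sel
    # residualize the candidate on the selected block
    fit_cand_on_sel, _ = _project_ss(Xc_sel, Xc_cand)
    R_cand = Xc_cand - fit_cand_on_sel
    Qc, Rr = np.linalg.qr(R_cand)
    diag = np.abs(np.diag(Rr))
    # rank tolerance relative to the candidate's original scale, so a
    # candidate fully absorbed by the selected block contributes nothing
    scale = np.linalg.norm(Xc_cand, axis=0).max() if Xc_cand.size else 0.0
    tol = max(R_cand.shape) * np.finfo(float).eps * max(scale, 1e-30) * 100
    Qc = Qc[:, diag > tol]
    df_added = Qc.shape[1]
    n = len(Y)
    resid_ss = float((resid**2).sum())

    def f_stat(R: np.ndarray) -> float:
        added = float(((Qc.T @ R) ** 2).sum())
        df_res = n - 1 - rank_sel - df_added
        if df_res <= 0:
            raise ValueError("no residual degrees of freedom")
        rss = float((R**2).sum()) - added
        if df_added == 0:
            return 0.0
        if rss <= 0:
            return np.inf
        return (added / df_added) / (rss / df_res)

    f_obs = f_stat(resid)
    rng = np.random.default_rng(seed)
    count_ge = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(idx)
        if f_stat(resid[idx]) >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return f_obs, p


def forward_select(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    method: str = "rda",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """Forward stepwise covariate selection with permutation pseudo-F stopping.

    At each step the candidate with the largest added inertia (conditioning
    on the current selection) is permutation-tested; it joins the model if
    its P <= alpha, otherwise selection stops.  An empty selection is a
    valid outcome.  The result's ``trail`` records every candidate's added
    inertia at every step, and the final fit uses the selected covariates.
    """
    candidates = list(X.columns)
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    selected: list[str] = []
    steps: list[SelectionStep] = []
    trail: list[dict[str, float]] = []
    blocks = _design_blocks(X)
    total = _fit(method, Y, np.empty((len(Y), 0)))[2]
    step_seed = seed
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        gains: dict[str, float] = {}
        for cand in remaining:
            cols = [blocks[v].to_numpy() for v in selected + [cand]]
            Xd = np.concatenate(cols, axis=1)
            Z, Xc, _, _ = _fit(method, Y, Xd)
            fitted, _ = _project_ss(Xc, Z)
            full = float((fitted**2).sum())
            if selected:
                cols_s = [blocks[v].to_numpy() for v in selected]
                Zs, Xcs, _, _ = _fit(method, Y, np.concatenate(cols_s, axis=1))
                fs, _ = _project_ss(Xcs, Zs)
                base = float((fs**2).sum())
            else:
                base = 0.0
            gains[cand] = full - base
        trail.append(dict(gains))
        best = max(gains, key=lambda c: gains[c])
        try:
            f_obs, p = permutation_pseudo_f(
                Y, X, selected, best, method=method, n_perm=n_perm,
                seed=step_seed)
        except ValueError:
            break  # no residual df left
        step_seed += 1
        if p <= alpha:
            selected.append(best)
            cols = [blocks[v].to_numpy() for v in selected]
            Zf, Xcf, _, _ = _fit(method, Y, np.concatenate(cols, axis=1))
            ff, _ = _project_ss(Xcf, Zf)
            cum = float((ff**2).sum()) / total
            df_b = blocks[best].shape[1]
            steps.append(SelectionStep(best, gains[best], f_obs, p, df_b, cum))
        else:
            break
    result = (_ordination(method, Y, X[selected]) if selected
              else OrdinationResult(method, total, 0.0, np.array([]),
                                    pd.DataFrame(index=Y.index)))
    result.selected = steps
    result.trail = trail
    return result
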