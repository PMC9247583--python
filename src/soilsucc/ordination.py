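"""Redundancy analysis (RDA) with permutation significance and hierarchical
partitioning of predictor importance.

RDA here is the classical two-step: Hellinger-transform the count table,
regress the centred community matrix on the standardised predictors, and
take the principal axes of the fitted values.  The constrained variance
fraction is tr(Yhat'Yhat)/tr(Yc'Yc); the adjusted fraction uses the Ezekiel
correction 1 - (1 - R^2)(n - 1)/(n - p - 1).  Significance comes from a
Monte Carlo permutation test (rows of Y permuted; 999 permutations by
default), and per-predictor importance from Chevan-Sutherland hierarchical
partitioning over all 2^p predictor subsets (the Shapley decomposition of
R^2, so the independent contributions sum exactly to the full-model value).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import OtuTable

MAX_HP_PREDICTORS = 15


@dataclass
class OrdinationResult:
    constrained_R2: float
    adjusted_R2: float
    eigenvalues: np.ndarray          # constrained axes, non-increasing
    site_scores: pd.DataFrame        # samples x axes
    predictor_scores: pd.DataFrame   # predictors x axes (correlations)
    global_p: float | None = None
    per_predictor_p: dict = field(default_factory=dict)


@dataclass
class HierPartResult:
    """Per-predictor independent contributions (sum = full-model R^2)."""

    contributions: pd.DataFrame  # predictor, independent_contribution, percent_of_explained
    full_model_r2: float
    adjusted: bool


def hellinger(table: OtuTable) -> np.ndarray:
    """sqrt of per-sample relative abundances; rows have unit squared sum."""
    depths = table.depths
    if (depths == 0).any():
        raise ValueError("zero-depth sample")
    return np.sqrt(table.counts / depths[:, None])


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _standardize(X: np.ndarray, names: list[str]) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    zero = [names[j] for j in np.flatnonzero(sd == 0)]
    if zero:
        raise ValueError(f"constant predictor column(s): {zero}")
    Xs = (X - X.mean(axis=0)) / sd
    r = np.linalg.matrix_rank(Xs)
    if r < Xs.shape[1]:
        # name columns involved in the dependency via pivoted QR
        from scipy.linalg import qr
        _, _, piv = qr(Xs, pivoting=True, mode="economic")
        collinear = sorted(names[j] for j in piv[r:])
        raise ValueError(f"predictors are rank-deficient; collinear column(s): {collinear}")
    return Xs


def fit_rda(Y, X, n_axes: int = 2) -> OrdinationResult:
    """Multivariate regression of (centred) Y on (standardised) X followed
    by an SVD of the fitted matrix.

    Requires n_samples > n_predictors + 1 and full-rank X.
    """
    Y, _ = _as_matrix(Y)
    X, xnames = _as_matrix(X)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    if n <= p + 1:
        raise ValueError(f"need n_samples > n_predictors + 1 (n={n}, p={p})")
    Xs = _standardize(X, xnames)
    Yc = Y - Y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    fitted = Xs @ coef
    total = float((Yc ** 2).sum())
    r2 = float((fitted ** 2).sum()) / total if total > 0 else 0.0
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    U, s, _ = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2 / (n - 1)
    k = min(n_axes, int((s > 1e-12 * max(s[0], 1.0)).sum()) or 1)
    axes = [f"RDA{i + 1}" for i in range(k)]
    sites = pd.DataFrame(U[:, :k] * s[:k], columns=axes)
    # predictor scores: correlation of each standardised predictor with axes
    site_arr = sites.to_numpy()
    denom = (np.linalg.norm(Xs, axis=0)[:, None]
             * np.linalg.norm(site_arr - site_arr.mean(0), axis=0)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (Xs.T @ (site_arr - site_arr.mean(0))) / denom
    pred_scores = pd.DataFrame(np.nan_to_num(pred), index=xnames, columns=axes)
    return OrdinationResult(r2, adj, eig[:k], sites, pred_scores)


def permutation_test(Y, X, n_perm: int = 999, seed: int = 0) -> dict:
    """Monte Carlo permutation test of the RDA.

    Global p: rows of Y permuted, p = (1 + #{perm R^2 >= observed}) /
    (n_perm + 1).  Per-predictor p-values come from marginal
    single-predictor RDAs under the same scheme.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Y, _ = _as_matrix(Y)
    X, xnames = _as_matrix(X)
    n = Y.shape[0]
    Xs = _standardize(X, xnames)
    Yc = Y - Y.mean(axis=0)
    total = float((Yc ** 2).sum())
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    def perm_p(Xcols: np.ndarray) -> float:
        Q, _ = np.linalg.qr(Xcols)
        obs = float(((Q.T @ Yc) ** 2).sum())
        null = np.array([((Q.T @ Yc[pi]) ** 2).sum() for pi in perms])
        return (1 + int((null >= obs - 1e-12 * max(obs, 1.0)).sum())) / (n_perm + 1)

    out = {"global_p": perm_p(Xs),
           "per_predictor_p": {name: perm_p(Xs[:, [j]])
                               for j, name in enumerate(xnames)},
           "n_perm": n_perm}
    return out


def significance_stars(p: float) -> str:
    """Table-style marks: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


def hierarchical_partition(Y, X, adjusted: bool = True) -> HierPartResult:
    """Chevan-Sutherland hierarchical partitioning of (adjusted) R^2.

    For each predictor j: average over hierarchy levels of the mean R^2
    increment from adding j to subsets lacking j.  This is the Shapley
    decomposition, so contributions sum to the full-model value to machine
    precision.  Enumerates all 2^p subsets; p is capped at 15.
    """
    Y, _ = _as_matrix(Y)
    X, xnames = _as_matrix(X)
    n, p = X.shape
    if p > MAX_HP_PREDICTORS:
        raise ValueError(
            f"{p} predictors means 2^{p} subsets; reduce to <= {MAX_HP_PREDICTORS}")
    if n <= p + 1:
        raise ValueError(f"need n_samples > n_predictors + 1 (n={n}, p={p})")
    Xs = _standardize(X, xnames)
    Yc = Y - Y.mean(axis=0)
    total = float((Yc ** 2).sum())
    G = Xs.T @ Xs
    C = Xs.T @ Yc

    r2: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for S in combinations(range(p), size):
            idx = list(S)
            GS = G[np.ix_(idx, idx)]
            CS = C[idx]
            sol = np.linalg.solve(GS, CS)
            val = float((CS * sol).sum()) / total
            if adjusted:
                val = 1 - (1 - val) * (n - 1) / (n - size - 1)
            r2[frozenset(S)] = val

    contrib = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        level_means = []
        for size in range(0, p):  # size of the subset j is added to
            incs = [r2[frozenset(S) | {j}] - r2[frozenset(S)]
                    for S in combinations(rest, size)]
            level_means.append(float(np.mean(incs)))
        contrib[j] = float(np.mean(level_means))
    full = r2[frozenset(range(p))]
    df = pd.DataFrame({
        "predictor": xnames,
        "independent_contribution": contrib,
        "percent_of_explained": 100 * contrib / full if full != 0 else np.nan,
    })
    return HierPartResult(df, full, adjusted)


def rda_analysis(table: OtuTable, env: pd.DataFrame, n_perm: int = 999,
                 seed: int = 0, adjusted_hp: bool = True) -> dict:
    """Convenience wrapper: Hellinger -> RDA -> permutation test -> HP."""
    Y = hellinger(table)
    res = fit_rda(Y, env)
    perm = permutation_test(Y, env, n_perm=n_perm, seed=seed)
    res.global_p = perm["global_p"]
    res.per_predictor_p = perm["per_predictor_p"]
    hp = hierarchical_partition(Y, env, adjusted=adjusted_hp)
    return {"ordination": res, "hierarchical_partition": hp, "permutation": perm}
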