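"""Constrained ordination and distance-based multivariate tests.

Redundancy analysis (RDA) is run on CLR-transformed abundances: the
fraction of total community variance explained by a (dummy-coded)
constraint, an adjusted R-squared, and a permutation p-value.  Partial
RDA residualizes both the response and the constraint on a conditioning
design first and permutes residuals under the reduced model
(Freedman-Lane).  PERMANOVA (ADONIS-style) partitions squared
Bray-Curtis distances among groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import ClrMatrix, Composition
from .tables_io import CountTable

__all__ = [
    "RdaResult",
    "PermanovaResult",
    "rda",
    "bray_curtis_matrix",
    "permanova",
    "pairwise_permanova",
]


@dataclass
class RdaResult:
    r2: float
    r2_adjusted: float
    pseudo_f: float
    p_perm: float
    n_samples: int
    n_constraint_df: int


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_perm: float
    n_samples: int
    n_groups: int


def _as_matrix(Y) -> np.ndarray:
    if isinstance(Y, ClrMatrix) or isinstance(Y, Composition):
        return np.asarray(Y.values, dtype=float)
    return np.asarray(Y, dtype=float)


def _design_matrix(x, name: str) -> np.ndarray:
    """Column-centred design matrix; categorical input is dummy-coded
    (first level dropped)."""
    arr = np.asarray(x)
    if arr.ndim == 1 and (arr.dtype.kind in "USO" or arr.dtype == bool):
        dummies = pd.get_dummies(pd.Series(arr), drop_first=True).to_numpy(float)
        if dummies.shape[1] == 0:
            raise ValueError(f"{name} has a single level; no constraint df")
        X = dummies
    else:
        X = np.asarray(arr, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    return X - X.mean(axis=0, keepdims=True)


def _orthonormal_basis(X: np.ndarray, name: str, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal column basis; raises naming dropped columns on collinearity."""
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > rtol * (s[0] if s.size else 1.0)))
    if rank < X.shape[1]:
        # identify columns not supported by the retained right singular vectors
        support = np.abs(vt[:rank]).sum(axis=0)
        dropped = [int(j) for j in np.flatnonzero(support < rtol)]
        raise ValueError(
            f"collinear {name} design after residualization "
            f"(rank {rank} < {X.shape[1]} columns; degenerate columns {dropped})"
        )
    return u[:, :rank]


def rda(
    Y,
    constraint,
    condition=None,
    n_perm: int = 999,
    seed: int = 0,
) -> RdaResult:
    """Redundancy analysis of a multivariate response on a constraint.

    ``Y`` is a ClrMatrix (or plain samples x variables array).  R-squared
    is the constrained fraction of the total (centred) variance;
    ``r2_adjusted = 1 - (1 - R2) (n - 1) / (n - 1 - p)`` with ``p`` the
    constraint degrees of freedom.  When ``condition`` is given, both the
    response and the constraint are residualized on the conditioning
    design (partial RDA) and permutations follow the Freedman-Lane
    scheme: residuals under the reduced model are permuted and the
    reduced-model fit added back.
    """
    Ym = _as_matrix(Y)
    n = Ym.shape[0]
    Yc = Ym - Ym.mean(axis=0, keepdims=True)
    ss_total = float((Yc**2).sum())
    if ss_total <= 0:
        raise ValueError("response has zero total variance")

    X = _design_matrix(constraint, "constraint")
    if condition is not None:
        Z = _design_matrix(condition, "condition")
        Qz = _orthonormal_basis(Z, "condition")
        df_cond = Qz.shape[1]
    else:
        Qz = None
        df_cond = 0

    def _fit(Yin: np.ndarray) -> tuple[float, float]:
        """(SS_fit, SS_res) of the constrained projection."""
        if Qz is not None:
            Yr = Yin - Qz @ (Qz.T @ Yin)
            Xr = X - Qz @ (Qz.T @ X)
        else:
            Yr, Xr = Yin, X
        Qx = _orthonormal_basis(Xr, "constraint")
        proj = Qx.T @ Yr
        ss_fit = float((proj**2).sum())
        ss_res = float((Yr**2).sum()) - ss_fit
        return ss_fit, ss_res

    # constraint rank / df established once on the observed design
    if Qz is not None:
        Xr0 = X - Qz @ (Qz.T @ X)
    else:
        Xr0 = X
    df_fit = _orthonormal_basis(Xr0, "constraint").shape[1]
    df_res = n - 1 - df_cond - df_fit
    if df_res <= 0:
        raise ValueError("not enough residual degrees of freedom")

    ss_fit, ss_res = _fit(Yc)
    r2 = ss_fit / ss_total
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - df_fit)
    with np.errstate(divide="ignore"):
        f_obs = float(np.float64(ss_fit / df_fit) / np.float64(ss_res / df_res))

    rng = np.random.default_rng(seed)
    if Qz is not None:
        reduced_fit = Qz @ (Qz.T @ Yc)
        reduced_res = Yc - reduced_fit
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if Qz is not None:
            Ystar = reduced_fit + reduced_res[perm]
        else:
            Ystar = Yc[perm]
        ss_f, ss_r = _fit(Ystar)
        with np.errstate(divide="ignore"):
            f_star = float(np.float64(ss_f / df_fit) / np.float64(ss_r / df_res))
        if f_star >= f_obs - 1e-9 * max(1.0, abs(f_obs)):
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return RdaResult(
        r2=float(r2),
        r2_adjusted=float(r2_adj),
        pseudo_f=float(f_obs),
        p_perm=float(p),
        n_samples=n,
        n_constraint_df=df_fit,
    )


def bray_curtis_matrix(table) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities ``sum|a-b| / sum(a+b)``."""
    if isinstance(table, CountTable):
        X = np.asarray(table.counts, dtype=float)
    elif isinstance(table, Composition):
        X = np.asarray(table.values, dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative values")
    totals = X.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples {zero.tolist()}"
        )
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i + 1:] - X[i]).sum(axis=1)
        den = (X[i + 1:] + X[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / den, np.nan)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    if np.isnan(d).any():
        raise ValueError("Bray-Curtis undefined for an all-zero sample pair")
    return d


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_between, SS_within) from squared distances, ADONIS partitioning."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, 1).sum()) / idx.size
    return ss_total - ss_within, ss_within


def permanova(
    dist: np.ndarray,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g))`` with the
    sums of squares computed from squared distances
    (``SS_total = sum_{i<j} d_ij^2 / n``, within-group terms divided by
    group size); the p-value permutes group labels.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray([str(g) for g in grouping])
    n = d.shape[0]
    if d.shape != (n, n) or labels.shape[0] != n:
        raise ValueError("distance matrix and grouping sizes disagree")
    groups, counts = np.unique(labels, return_counts=True)
    g = groups.size
    if g < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = groups[counts < 2].tolist()
        raise ValueError(f"singleton group(s): {small}")
    d2 = d * d
    ss_b, ss_w = _permanova_ss(d2, labels)
    ss_total = ss_b + ss_w
    f_obs = (ss_b / (g - 1)) / (ss_w / (n - g))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        b, w = _permanova_ss(d2, perm_labels)
        f_star = (b / (g - 1)) / (w / (n - g))
        if f_star >= f_obs - 1e-9 * max(1.0, abs(f_obs)):
            exceed += 1
    return PermanovaResult(
        r2=float(ss_b / ss_total),
        pseudo_f=float(f_obs),
        p_perm=float((1.0 + exceed) / (n_perm + 1.0)),
        n_samples=n,
        n_groups=int(g),
    )


def pairwise_permanova(
    dist: np.ndarray,
    grouping: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    adjust: bool = False,
) -> pd.DataFrame:
    """Two-group PERMANOVAs for every pair of levels, each on its sample subset.

    Benjamini-Hochberg adjustment across the pairwise family is optional.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray([str(g) for g in grouping])
    levels = sorted(set(labels))
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in combinations(levels, 2):
        idx = np.flatnonzero((labels == a) | (labels == b))
        sub = d[np.ix_(idx, idx)]
        res = permanova(sub, labels[idx], n_perm=n_perm,
                        seed=int(rng.integers(2**31 - 1)))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "r2": res.r2,
                "pseudo_f": res.pseudo_f,
                "p_perm": res.p_perm,
                "n": int(idx.size),
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out
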