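"""Alpha diversity and the paired nonparametric comparisons built on it.

Chao1 richness and Shannon diversity are computed per rarefied sample;
baseline-vs-treatment contrasts use the Wilcoxon signed-rank test with
pairing by steer (the crossover design makes every steer its own
control), and the fungal/bacterial diversity relationship is summarised
by Spearman's rank correlation.

The signed-rank test is implemented with an exact tie-aware null
(dynamic programming over midranks) for up to 25 effective pairs and a
tie-corrected normal approximation beyond that; scipy's exact path does
not handle midranks, which the matched sparse-count data here routinely
produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CountTable, SampleMetadata

__all__ = [
    "chao1",
    "shannon",
    "alpha_diversity_table",
    "wilcoxon_signed_rank",
    "spearman_correlation",
    "pair_by_steer",
]


def chao1(counts: Sequence[float], bias_corrected_only_when_needed: bool = True) -> float:
    """Chao1 richness estimator.

    Classic form ``S_obs + F1^2 / (2 F2)`` with singleton/doubleton counts
    F1/F2; when F2 = 0 the bias-corrected form
    ``S_obs + F1 (F1 - 1) / 2`` is used instead.  Setting
    ``bias_corrected_only_when_needed=False`` applies the bias-corrected
    estimator ``S_obs + F1(F1-1) / (2 (F2+1))`` throughout.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("chao1 undefined for an all-zero sample")
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if not bias_corrected_only_when_needed:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon diversity ``-sum p_i log p_i`` (natural log by default)."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon indices as a DataFrame."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        c = table.counts[i]
        rows.append(
            {"sample_id": sid, "chao1": chao1(c), "shannon": shannon(c)}
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank, exact with midranks
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic with midranks.

    Enumerates the null distribution of ``W+`` by dynamic programming on
    doubled (hence integer) midranks; the distribution is symmetric about
    ``sum(ranks) / 2`` so the two-sided p is the symmetric tail sum.
    """
    r2 = np.round(2 * ranks).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    # dist[v] = number of sign assignments with doubled W+ equal to v
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    # two-sided: P(|W - mu| >= |w - mu|) via the symmetric pair of tails
    hi = max(w2, total - w2)
    lo = min(w2, total - w2)
    return float(min(1.0, dist[hi:].sum() + dist[: lo + 1].sum()))


def wilcoxon_signed_rank(
    paired_a: Mapping[str, float],
    paired_b: Mapping[str, float],
    exact_threshold: int = 25,
) -> tuple[float, float]:
    """Matched-pairs Wilcoxon signed-rank test.

    ``paired_a`` and ``paired_b`` are keyed by steer; steers missing from
    either side are dropped with a warning.  Zero differences are dropped
    (Wilcoxon convention) and tied absolute differences receive midranks.
    Returns ``(W+, two-sided p)`` with an exact enumeration for up to
    ``exact_threshold`` effective pairs and a tie-corrected normal
    approximation above.
    """
    common = sorted(set(paired_a) & set(paired_b))
    if not common:
        raise ValueError("no overlapping steers between the two groups")
    dropped = (set(paired_a) | set(paired_b)) - set(common)
    if dropped:
        warnings.warn(
            f"dropping unmatched steers: {sorted(dropped)}", stacklevel=2
        )
    d = np.array([float(paired_a[k]) - float(paired_b[k]) for k in common])
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        mu = ranks.sum() / 2.0
        sigma = float(np.sqrt(np.sum(ranks**2) / 4.0))
        if sigma == 0:
            raise ValueError("degenerate signed-rank variance")
        z = (w_plus - mu) / sigma
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_plus, p


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("zero variance in ranks; Spearman undefined")
    return float((rx * ry).sum() / denom)


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 9
) -> tuple[float, float]:
    """Spearman's rho with a two-sided p-value.

    Rho is the Pearson correlation of midranks.  For ``n <= exact_threshold``
    the p-value enumerates all permutations of one rank vector; above that
    it uses the usual ``t = rho sqrt((n-2)/(1-rho^2))`` approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rho = _rank_pearson(x, y)
    if n <= exact_threshold:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.fromiter(
            (i for perm in permutations(range(n)) for i in perm), dtype=np.intp
        ).reshape(-1, n)
        mat = ry[perms]  # all rank rearrangements, (n!, n)
        rxc = rx - rx.mean()
        mc = mat - mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (mc**2).sum(axis=1))
        rhos = (mc @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(min(1.0, p))


# ---------------------------------------------------------------------------
# pairing helper
# ---------------------------------------------------------------------------

def pair_by_steer(
    values: Mapping[str, float],
    meta: Sequence[SampleMetadata],
    selector,
) -> dict[str, float]:
    """Collapse per-sample values to one value per steer for the samples
    matching ``selector`` (a predicate on a SampleMetadata record),
    averaging a steer's replicate samples within the selected phase."""
    per_steer: dict[str, list[float]] = {}
    for m in meta:
        if m.sample_id in values and selector(m):
            per_steer.setdefault(m.steer_id, []).append(float(values[m.sample_id]))
    return {s: float(np.mean(v)) for s, v in per_steer.items()}
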