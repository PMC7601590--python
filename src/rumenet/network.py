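"""Ensemble cross-kingdom co-occurrence network inference.

The procedure scores every fungus-bacterium pair with four association
measures (Spearman rho, Kendall tau-b, Bray-Curtis dissimilarity,
symmetrized Kullback-Leibler divergence on across-sample profiles),
builds a permutation null for each pair and measure by the ReBoot
scheme -- the two taxa are shuffled across samples and, for Spearman,
the per-sample compositions are re-closed with the shuffled values in
place, which discounts associations that are mere artefacts of closure
-- and a bootstrap distribution by resampling samples with replacement.
Each measure's p-value is the two-sided Gaussian tail probability of the
null mean under a normal curve with the bootstrap mean and standard
deviation; measure p-values sharing the majority direction are merged
with Brown's method (Fisher's combination corrected for the empirical
dependence of the -2 ln p statistics), corrected across pairs by
Benjamini-Hochberg, and an edge is retained when it is supported by at
least ``min_support`` measures, its FDR q is below ``alpha``, and the
observed scores sit inside their bootstrap confidence intervals.

Hubs are the top-k nodes by degree per network; the union over the
overall / bloat / no-bloat networks gives the hub set carried into the
downstream ordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import closure, filter_prevalence
from .tables_io import Bloat, CountTable, EdgeRecord, SampleMetadata, Treatment

__all__ = [
    "MEASURES",
    "MeasureScore",
    "CoNetwork",
    "NetworkInput",
    "association_score",
    "reboot_null",
    "bootstrap_distribution",
    "measure_pvalue",
    "browns_merge",
    "bh_fdr",
    "prepare_network_input",
    "build_network",
    "infer_network",
    "find_hubs",
    "hub_union",
    "exclusion_fraction",
]

MEASURES = ("SPEARMAN", "KENDALL", "BRAY_CURTIS", "KLD")
_CORRELATIONS = ("SPEARMAN", "KENDALL")
COPRESENCE = "COPRESENCE"
EXCLUSION = "EXCLUSION"
NONE = "NONE"

_KLD_EPS = 1e-6
_P_FLOOR = 1e-300


@dataclass
class MeasureScore:
    """Scores and resampling summaries of one measure for one taxon pair."""

    measure: str
    observed: float
    null_mean: float
    null_sd: float
    boot_mean: float
    boot_sd: float
    boot_ci: tuple[float, float]
    p: float = 1.0
    direction: str = NONE


@dataclass
class CoNetwork:
    """A retained co-occurrence network plus its candidate-level table."""

    nodes: dict[str, str]            # taxon -> kingdom
    edges: list[EdgeRecord]
    stratum: str = "overall"
    n_candidates: int = 0
    candidates: Optional[pd.DataFrame] = field(default=None, repr=False)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for e in self.edges:
            deg[e.fungal_taxon] = deg.get(e.fungal_taxon, 0) + 1
            deg[e.bacterial_taxon] = deg.get(e.bacterial_taxon, 0) + 1
        return deg

    def strength(self) -> dict[str, float]:
        """Summed edge strength (-ln merged p) per node, used to break degree ties."""
        out: dict[str, float] = {}
        for e in self.edges:
            w = -float(np.log(max(e.p_merged, _P_FLOOR)))
            out[e.fungal_taxon] = out.get(e.fungal_taxon, 0.0) + w
            out[e.bacterial_taxon] = out.get(e.bacterial_taxon, 0.0) + w
        return out


# ---------------------------------------------------------------------------
# single-pair reference operations
# ---------------------------------------------------------------------------

def _kld_profiles(x: np.ndarray, y: np.ndarray, eps: float = _KLD_EPS):
    p = (x + eps) / (x + eps).sum()
    q = (y + eps) / (y + eps).sum()
    return p, q


def association_score(x, y, measure: str, kld_eps: float = _KLD_EPS) -> float:
    """Score one taxon pair with one of the four ensemble measures.

    ``x`` and ``y`` are per-sample relative abundances.  Correlation
    measures return NaN when a vector has zero rank variance (the pair is
    then skipped for that measure).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("x and y must be equal-length vectors with >= 4 samples")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("relative abundances must be non-negative")
    if measure == "SPEARMAN":
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0:
            return float("nan")
        return float(np.corrcoef(rx, ry)[0, 1])
    if measure == "KENDALL":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return float("nan")
        return float(stats.kendalltau(x, y, variant="b").statistic)
    if measure == "BRAY_CURTIS":
        denom = float((x + y).sum())
        if denom == 0:
            return float("nan")
        return float(np.abs(x - y).sum() / denom)
    if measure == "KLD":
        p, q = _kld_profiles(x, y, kld_eps)
        return float(0.5 * ((p - q) * (np.log(p) - np.log(q))).sum())
    raise ValueError(f"unknown measure {measure!r}")


def reboot_null(
    pair: tuple[np.ndarray, np.ndarray],
    table_context: np.ndarray | None,
    measure: str,
    b_perm: int = 1000,
    seed: int = 0,
    renormalize: bool | None = None,
) -> tuple[float, float]:
    """ReBoot permutation null mean and standard deviation for one pair.

    Each iteration independently shuffles the two taxa across samples; for
    the Spearman measure (by default) the shuffled values are put back into
    the sample compositions, which are re-closed before scoring.
    ``table_context`` gives the per-sample total of the full composition
    (or the composition matrix itself) so the "rest" of each sample is
    known; when None the pair is treated as embedded in unit-sum rows.
    """
    if b_perm < 100:
        warnings.warn("b_perm < 100 gives an unstable null", stacklevel=2)
    x, y = (np.asarray(v, dtype=float) for v in pair)
    n = x.size
    if renormalize is None:
        renormalize = measure == "SPEARMAN"
    if table_context is None:
        row_totals = np.ones(n)
    elif np.ndim(table_context) == 2:
        row_totals = np.asarray(table_context, dtype=float).sum(axis=1)
    else:
        row_totals = np.asarray(table_context, dtype=float)
    rest = row_totals - x - y
    rng = np.random.default_rng(seed)
    vals = np.empty(b_perm)
    for b in range(b_perm):
        xs = x[rng.permutation(n)]
        ys = y[rng.permutation(n)]
        if renormalize:
            tot = rest + xs + ys
            xs, ys = xs / tot, ys / tot
        vals[b] = association_score(xs, ys, measure)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), float("nan")
    return float(vals.mean()), float(vals.std(ddof=1))


def bootstrap_distribution(
    pair: tuple[np.ndarray, np.ndarray],
    measure: str,
    b_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Bootstrap mean, sd and percentile CI of a pair's score.

    Samples are resampled with replacement (the pair stays aligned);
    degenerate resamples with zero variance are skipped and counted.
    """
    x, y = (np.asarray(v, dtype=float) for v in pair)
    n = x.size
    if n < 8:
        raise ValueError("bootstrap requires at least 8 samples")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(b_boot):
        idx = rng.integers(0, n, n)
        v = association_score(x[idx], y[idx], measure)
        if np.isnan(v):
            skipped += 1
        else:
            vals.append(v)
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate bootstrap resamples",
                      stacklevel=2)
    if not vals:
        return float("nan"), float("nan"), (float("nan"), float("nan"))
    vals = np.asarray(vals)
    a = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(vals, [a, 1.0 - a])
    return float(vals.mean()), float(vals.std(ddof=1)), (float(lo), float(hi))


def measure_pvalue(score: MeasureScore, two_sided: bool = True) -> float:
    """Gaussian tail probability of the null mean under the bootstrap curve.

    ``z = (null_mean - boot_mean) / boot_sd``; the p-value is two-sided
    by default (``two_sided=False`` gives the tail in the observed
    direction only).  The measure's direction is set from the observed
    score: sign for correlations, observed-vs-null for the
    dissimilarities (greater than expected => mutual exclusion).
    """
    if not np.isfinite(score.boot_sd) or score.boot_sd <= 0:
        score.p = float("nan")
        score.direction = NONE
        return score.p
    z = (score.null_mean - score.boot_mean) / score.boot_sd
    tail = float(stats.norm.sf(abs(z)))
    p = 2.0 * tail if two_sided else tail
    score.p = float(max(min(p, 1.0), _P_FLOOR))
    if score.measure in _CORRELATIONS:
        if score.observed > 0:
            score.direction = COPRESENCE
        elif score.observed < 0:
            score.direction = EXCLUSION
        else:
            score.direction = NONE
    else:
        if score.observed > score.null_mean:
            score.direction = EXCLUSION
        elif score.observed < score.null_mean:
            score.direction = COPRESENCE
        else:
            score.direction = NONE
    return score.p


def browns_merge(p_values: Sequence[float], cov: np.ndarray | None = None) -> float:
    """Brown's method for combining dependent p-values.

    ``X = sum -2 ln p_i`` has mean ``E = 2k`` and variance
    ``Var = 4k + 2 sum_{i<j} cov_ij`` where ``cov_ij`` is the covariance
    of the ``-2 ln p`` statistics; the merged p is the upper tail of
    ``X / c`` under a chi-square with ``f = 2 E^2 / Var`` degrees of
    freedom, ``c = Var / (2 E)``.  With zero covariances this is exactly
    Fisher's method; with perfectly dependent duplicates (cov = 4) it
    collapses to the single p.
    """
    p = np.asarray([max(float(v), _P_FLOOR) for v in p_values])
    k = p.size
    if k == 0:
        raise ValueError("need at least one p-value")
    x = float((-2.0 * np.log(p)).sum())
    e = 2.0 * k
    cov_sum = 0.0
    if cov is not None and k > 1:
        cov = np.asarray(cov, dtype=float)
        iu = np.triu_indices(k, 1)
        terms = cov[iu]
        if np.any((terms < -1e-9) | (terms > 4.0 + 1e-9)):
            warnings.warn(
                "Brown covariance terms outside [0, 4]; clipping", stacklevel=2
            )
        terms = np.clip(terms, 0.0, 4.0)
        cov_sum = float(terms.sum())
    var = 4.0 * k + 2.0 * cov_sum
    c = var / (2.0 * e)
    f = 2.0 * e * e / var
    return float(max(stats.chi2.sf(x / c, f), _P_FLOOR))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# vectorized ensemble engine
# ---------------------------------------------------------------------------

@dataclass
class NetworkInput:
    """Aligned relative-abundance context for the ensemble.

    ``rel`` holds the concatenated fungal+bacterial composition (each
    kingdom closed to one, then jointly re-closed so rows sum to one).
    """

    sample_ids: list[str]
    fungal_ids: list[str]
    bacterial_ids: list[str]
    rel: np.ndarray  # (n_samples, n_fungal + n_bacterial)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def fungal_block(self) -> np.ndarray:
        return self.rel[:, : len(self.fungal_ids)]

    def bacterial_block(self) -> np.ndarray:
        return self.rel[:, len(self.fungal_ids):]


def prepare_network_input(
    fungal: CountTable,
    bacterial: CountTable,
    min_prevalence: float = 0.5,
) -> NetworkInput:
    """Align samples, apply the prevalence filter per kingdom, and build the
    joint composition used by the ensemble and its ReBoot renormalization."""
    common = [s for s in fungal.sample_ids if s in set(bacterial.sample_ids)]
    if len(common) < 8:
        raise ValueError("fewer than 8 samples shared between the two tables")
    f_idx = [fungal.sample_ids.index(s) for s in common]
    b_idx = [bacterial.sample_ids.index(s) for s in common]
    f = fungal.select_samples(f_idx)
    b = bacterial.select_samples(b_idx)
    f = filter_prevalence(f, min_prevalence)
    b = filter_prevalence(b, min_prevalence)
    rel = np.hstack([closure(f.counts), closure(b.counts)]) / 2.0
    return NetworkInput(common, list(f.taxon_ids), list(b.taxon_ids), rel)


def _rank_cols(M: np.ndarray) -> np.ndarray:
    return stats.rankdata(M, axis=0)


def _standardize_cols(M: np.ndarray) -> np.ndarray:
    """Column z-scores; zero-variance columns become NaN."""
    Mc = M - M.mean(axis=0, keepdims=True)
    sd = np.sqrt((Mc**2).sum(axis=0, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, Mc / sd, np.nan)


def _sign_matrices(M: np.ndarray) -> np.ndarray:
    """Per-taxon antisymmetric sign matrices: S[t, a, b] = sign(M[a,t]-M[b,t])."""
    diff = M.T[:, :, None] - M.T[:, None, :]
    return np.sign(diff).astype(np.int8)


def _kendall_matrix(Sf_flat, Sb_flat, nf_untied, nb_untied) -> np.ndarray:
    """tau-b between every fungal/bacterial taxon from flattened sign matrices."""
    cd = 0.5 * (Sf_flat @ Sb_flat.T)
    denom = np.sqrt(np.outer(nf_untied, nb_untied))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, cd / denom, np.nan)


def _bc_matrix(F: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = np.abs(F[:, :, None] - B[:, None, :]).sum(axis=0)
    den = F.sum(axis=0)[:, None] + B.sum(axis=0)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _kld_matrix(F: np.ndarray, B: np.ndarray, eps: float = _KLD_EPS) -> np.ndarray:
    P = (F + eps) / (F + eps).sum(axis=0, keepdims=True)
    Q = (B + eps) / (B + eps).sum(axis=0, keepdims=True)
    lP, lQ = np.log(P), np.log(Q)
    diff = P[:, :, None] - Q[:, None, :]
    ldiff = lP[:, :, None] - lQ[:, None, :]
    return 0.5 * (diff * ldiff).sum(axis=0)


def _observed_scores(inp: NetworkInput) -> dict[str, np.ndarray]:
    F = inp.fungal_block()
    B = inp.bacterial_block()
    zf = _standardize_cols(_rank_cols(F))
    zb = _standardize_cols(_rank_cols(B))
    spearman = zf.T @ np.nan_to_num(zb)
    spearman[:, np.isnan(zb[0])] = np.nan
    spearman[np.isnan(zf[0]), :] = np.nan
    S_all = _sign_matrices(inp.rel)
    nf = len(inp.fungal_ids)
    n = inp.n_samples
    S_flat = S_all.reshape(S_all.shape[0], n * n).astype(np.float64)
    untied = 0.5 * np.abs(S_flat).sum(axis=1)  # n0 - n1 per taxon
    kendall = _kendall_matrix(S_flat[:nf], S_flat[nf:], untied[:nf], untied[nf:])
    return {
        "SPEARMAN": spearman,
        "KENDALL": kendall,
        "BRAY_CURTIS": _bc_matrix(F, B),
        "KLD": _kld_matrix(F, B),
        "_S_all": S_all,
        "_untied": untied,
    }


def _pearson_last_axis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    num = (am * bm).sum(axis=-1)
    den = np.sqrt((am**2).sum(axis=-1) * (bm**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _null_stats(
    inp: NetworkInput,
    b_perm: int,
    rng: np.random.Generator,
    renormalize_measures: tuple[str, ...] = ("SPEARMAN",),
    chunk: int = 40,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-pair ReBoot null mean and sd for each measure.

    Measures listed in ``renormalize_measures`` shuffle both taxa
    independently and re-close each sample's composition before scoring;
    the remaining measures shuffle the pair alignment directly (a single
    relative permutation, which has the same null distribution as two
    independent shuffles for alignment-only statistics).
    """
    F = inp.fungal_block()
    B = inp.bacterial_block()
    n, nf, nb = inp.n_samples, F.shape[1], B.shape[1]
    row_rest_base = inp.rel.sum(axis=1)  # == 1 per construction
    S_all = _sign_matrices(inp.rel)
    untied = 0.5 * np.abs(
        S_all.reshape(S_all.shape[0], -1).astype(np.float32)
    ).sum(axis=1)

    # KLD profiles are fixed per taxon; only the alignment is shuffled
    Pf = (F + _KLD_EPS) / (F + _KLD_EPS).sum(axis=0, keepdims=True)
    Qb = (B + _KLD_EPS) / (B + _KLD_EPS).sum(axis=0, keepdims=True)
    lPf, lQb = np.log(Pf), np.log(Qb)
    bc_den = F.sum(axis=0)[:, None] + B.sum(axis=0)[None, :]

    out = {
        m: (np.full((nf, nb), np.nan), np.full((nf, nb), np.nan))
        for m in MEASURES
    }

    for i in range(nf):
        xi = F[:, i]
        for j0 in range(0, nb, chunk):
            j1 = min(j0 + chunk, nb)
            m = j1 - j0
            Bc = B[:, j0:j1]  # (n, m)

            # --- single relative permutation for alignment-only measures
            sigma = np.argsort(rng.random((m, b_perm, n)), axis=-1)
            xi_s = xi[sigma]  # (m, b_perm, n)

            # Bray-Curtis
            num = np.abs(xi_s - Bc.T[:, None, :]).sum(axis=-1)
            den = bc_den[i, j0:j1][:, None]
            bc_vals = num / den
            out["BRAY_CURTIS"][0][i, j0:j1] = bc_vals.mean(axis=1)
            out["BRAY_CURTIS"][1][i, j0:j1] = bc_vals.std(axis=1, ddof=1)

            # symmetrized KLD on fixed profiles, shuffled alignment
            p_s = Pf[:, i][sigma]
            lp_s = lPf[:, i][sigma]
            kld_vals = 0.5 * (
                (p_s - Qb.T[j0:j1, None, :]) * (lp_s - lQb.T[j0:j1, None, :])
            ).sum(axis=-1)
            out["KLD"][0][i, j0:j1] = kld_vals.mean(axis=1)
            out["KLD"][1][i, j0:j1] = kld_vals.std(axis=1, ddof=1)

            # Kendall tau-b: tie pattern (hence denominator) is permutation-
            # invariant, so only the concordance count is resampled
            if "KENDALL" in renormalize_measures:
                ken = _null_corr_renorm(
                    xi, Bc, row_rest_base, rng, b_perm, kendall=True
                )
            else:
                Sxi = S_all[i].astype(np.float32)
                Sy = S_all[nf + j0: nf + j1].astype(np.float32)
                cd = np.empty((m, b_perm))
                for jj in range(m):
                    perm = sigma[jj]
                    Sx_p = Sxi[perm[:, :, None], perm[:, None, :]]
                    cd[jj] = 0.5 * (Sx_p * Sy[jj][None, :, :]).sum(axis=(1, 2))
                denom = np.sqrt(untied[i] * untied[nf + j0: nf + j1])
                with np.errstate(invalid="ignore", divide="ignore"):
                    ken = np.where(denom[:, None] > 0, cd / denom[:, None], np.nan)
            out["KENDALL"][0][i, j0:j1] = np.nanmean(ken, axis=1)
            out["KENDALL"][1][i, j0:j1] = np.nanstd(ken, axis=1, ddof=1)

            # Spearman with ReBoot renormalization
            if "SPEARMAN" in renormalize_measures:
                sp = _null_corr_renorm(xi, Bc, row_rest_base, rng, b_perm)
            else:
                rx = stats.rankdata(xi_s, axis=-1)
                ry = stats.rankdata(Bc.T, axis=-1)[:, None, :]
                sp = _pearson_last_axis(rx, np.broadcast_to(ry, rx.shape))
            out["SPEARMAN"][0][i, j0:j1] = np.nanmean(sp, axis=1)
            out["SPEARMAN"][1][i, j0:j1] = np.nanstd(sp, axis=1, ddof=1)
    return out


def _null_corr_renorm(
    xi: np.ndarray,
    Bc: np.ndarray,
    row_totals: np.ndarray,
    rng: np.random.Generator,
    b_perm: int,
    kendall: bool = False,
) -> np.ndarray:
    """Renormalized-shuffle null values of a rank correlation: both taxa are
    shuffled independently, the composition is re-closed, then scored."""
    n = xi.size
    m = Bc.shape[1]
    p1 = np.argsort(rng.random((m, b_perm, n)), axis=-1)
    p2 = np.argsort(rng.random((m, b_perm, n)), axis=-1)
    xs = xi[p1]
    ys = np.take_along_axis(
        np.broadcast_to(Bc.T[:, None, :], (m, b_perm, n)), p2, axis=-1
    )
    rest = (row_totals[None, :] - xi[None, :] - Bc.T)[:, None, :]
    tot = rest + xs + ys
    a = xs / tot
    b = ys / tot
    if kendall:
        out = np.empty((m, b_perm))
        for jj in range(m):  # pair-wise to bound the (b_perm, n, n) temporaries
            dx = np.sign(a[jj][:, :, None] - a[jj][:, None, :])
            dy = np.sign(b[jj][:, :, None] - b[jj][:, None, :])
            cd = 0.5 * (dx * dy).sum(axis=(-2, -1))
            n1 = 0.5 * np.abs(dx).sum(axis=(-2, -1))
            n2 = 0.5 * np.abs(dy).sum(axis=(-2, -1))
            denom = np.sqrt(n1 * n2)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[jj] = np.where(denom > 0, cd / denom, np.nan)
        return out
    ra = stats.rankdata(a, axis=-1)
    rb = stats.rankdata(b, axis=-1)
    return _pearson_last_axis(ra, rb)


def _bootstrap_scores(
    inp: NetworkInput,
    b_boot: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Bootstrap score distributions, shape (b_boot, n_fungal, n_bacterial).

    One resample of the sample set per iteration; every pair's four scores
    are recomputed on the resampled table.
    """
    F = inp.fungal_block()
    B = inp.bacterial_block()
    n, nf, nb = inp.n_samples, F.shape[1], B.shape[1]
    S_all = _sign_matrices(inp.rel)
    boot = {m: np.empty((b_boot, nf, nb), dtype=np.float32) for m in MEASURES}
    for it in range(b_boot):
        idx = rng.integers(0, n, n)
        Fs, Bs = F[idx], B[idx]
        zf = _standardize_cols(_rank_cols(Fs))
        zb = _standardize_cols(_rank_cols(Bs))
        sp = np.nan_to_num(zf).T @ np.nan_to_num(zb)
        sp[np.isnan(zf[0]), :] = np.nan
        sp[:, np.isnan(zb[0])] = np.nan
        boot["SPEARMAN"][it] = sp
        Sr = S_all[:, idx[:, None], idx[None, :]]
        Sr_flat = Sr.reshape(Sr.shape[0], -1).astype(np.float32)
        untied = 0.5 * np.abs(Sr_flat).sum(axis=1)
        boot["KENDALL"][it] = _kendall_matrix(
            Sr_flat[:nf], Sr_flat[nf:], untied[:nf], untied[nf:]
        )
        boot["BRAY_CURTIS"][it] = _bc_matrix(Fs, Bs)
        boot["KLD"][it] = _kld_matrix(Fs, Bs)
    return boot


def infer_network(
    inp: NetworkInput,
    b_perm: int = 1000,
    b_boot: int = 1000,
    alpha: float = 0.05,
    min_support: int = 3,
    ci_level: float = 0.95,
    renormalize_measures: tuple[str, ...] = ("SPEARMAN",),
    seed: int = 0,
    stratum: str = "overall",
) -> CoNetwork:
    """Run the full ensemble on a prepared input and return the network."""
    root = np.random.SeedSequence(seed)
    s_null, s_boot = root.spawn(2)
    observed = _observed_scores(inp)
    nulls = _null_stats(
        inp, b_perm, np.random.default_rng(s_null),
        renormalize_measures=renormalize_measures,
    )
    boot = _bootstrap_scores(inp, b_boot, np.random.default_rng(s_boot))

    nf, nb = len(inp.fungal_ids), len(inp.bacterial_ids)
    a_tail = (1.0 - ci_level) / 2.0

    boot_mean = {m: np.nanmean(boot[m], axis=0) for m in MEASURES}
    boot_sd = {m: np.nanstd(boot[m], axis=0, ddof=1) for m in MEASURES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        boot_lo = {
            m: np.nanquantile(boot[m].astype(float), a_tail, axis=0)
            for m in MEASURES
        }
        boot_hi = {
            m: np.nanquantile(boot[m].astype(float), 1.0 - a_tail, axis=0)
            for m in MEASURES
        }

    candidates = build_candidate_table(
        inp, observed, nulls, boot_mean, boot_sd, boot_lo, boot_hi
    )
    return build_network(
        candidates,
        inp,
        alpha=alpha,
        min_support=min_support,
        stratum=stratum,
    )


def build_candidate_table(
    inp: NetworkInput,
    observed: dict[str, np.ndarray],
    nulls: dict[str, tuple[np.ndarray, np.ndarray]],
    boot_mean: dict[str, np.ndarray],
    boot_sd: dict[str, np.ndarray],
    boot_lo: dict[str, np.ndarray],
    boot_hi: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-pair per-measure p-values, directions and CI flags as a flat table."""
    nf, nb = len(inp.fungal_ids), len(inp.bacterial_ids)
    rows = []
    for i in range(nf):
        for j in range(nb):
            row: dict = {
                "fungal_taxon": inp.fungal_ids[i],
                "bacterial_taxon": inp.bacterial_ids[j],
            }
            for m in MEASURES:
                score = MeasureScore(
                    measure=m,
                    observed=float(observed[m][i, j]),
                    null_mean=float(nulls[m][0][i, j]),
                    null_sd=float(nulls[m][1][i, j]),
                    boot_mean=float(boot_mean[m][i, j]),
                    boot_sd=float(boot_sd[m][i, j]),
                    boot_ci=(float(boot_lo[m][i, j]), float(boot_hi[m][i, j])),
                )
                if not np.isfinite(score.observed) or not np.isfinite(
                    score.null_mean
                ):
                    row[f"p_{m}"] = np.nan
                    row[f"dir_{m}"] = NONE
                    row[f"ci_{m}"] = False
                    continue
                measure_pvalue(score)
                row[f"p_{m}"] = score.p
                row[f"dir_{m}"] = score.direction
                row[f"ci_{m}"] = bool(
                    score.boot_ci[0] - 1e-12
                    <= score.observed
                    <= score.boot_ci[1] + 1e-12
                )
                row[f"obs_{m}"] = score.observed
            rows.append(row)
    return pd.DataFrame(rows)


def build_network(
    candidates: pd.DataFrame,
    inp: NetworkInput | None = None,
    alpha: float = 0.05,
    min_support: int = 3,
    stratum: str = "overall",
) -> CoNetwork:
    """Merge measure p-values per pair, apply BH across pairs, keep edges.

    Per pair the measures are partitioned by direction; support is counted
    within the majority direction (ties broken toward the side with the
    stronger summed evidence), the merged p is Brown's combination of the
    supporting measures' p-values with the covariance of their
    ``-2 ln p`` statistics estimated across all candidate pairs, and an
    edge is retained iff support >= ``min_support``, BH q < ``alpha`` and
    the supporting observed scores sit within their bootstrap CIs.
    """
    df = candidates.copy()
    # empirical covariance of -2 ln p across candidate pairs, per measure pair
    neg2 = {}
    for m in MEASURES:
        with np.errstate(invalid="ignore", divide="ignore"):
            neg2[m] = -2.0 * np.log(df[f"p_{m}"].to_numpy(float))
    cov_full = np.zeros((len(MEASURES), len(MEASURES)))
    for a in range(len(MEASURES)):
        for b in range(a + 1, len(MEASURES)):
            va, vb = neg2[MEASURES[a]], neg2[MEASURES[b]]
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() >= 3:
                c = float(np.cov(va[ok], vb[ok])[0, 1])
            else:
                c = 0.0
            cov_full[a, b] = cov_full[b, a] = np.clip(c, 0.0, 4.0)

    merged = np.full(len(df), np.nan)
    support = np.zeros(len(df), dtype=int)
    direction = np.array([NONE] * len(df), dtype=object)
    sup_measures: list[tuple[str, ...]] = []
    ci_ok = np.zeros(len(df), dtype=bool)
    for r in range(len(df)):
        row = df.iloc[r]
        by_dir: dict[str, list[int]] = {COPRESENCE: [], EXCLUSION: []}
        for mi, m in enumerate(MEASURES):
            p = row[f"p_{m}"]
            d = row[f"dir_{m}"]
            if np.isfinite(p) and d in by_dir:
                by_dir[d].append(mi)
        if not by_dir[COPRESENCE] and not by_dir[EXCLUSION]:
            sup_measures.append(())
            continue
        nc, ne = len(by_dir[COPRESENCE]), len(by_dir[EXCLUSION])
        if nc > ne:
            maj = COPRESENCE
        elif ne > nc:
            maj = EXCLUSION
        else:  # tie: side with stronger summed evidence
            ev = {
                d: sum(-np.log(max(row[f"p_{MEASURES[mi]}"], _P_FLOOR))
                       for mi in idxs)
                for d, idxs in by_dir.items()
            }
            maj = max(ev, key=ev.get)
        idxs = by_dir[maj]
        ps = [row[f"p_{MEASURES[mi]}"] for mi in idxs]
        merged[r] = browns_merge(ps, cov_full[np.ix_(idxs, idxs)])
        support[r] = len(idxs)
        direction[r] = maj
        sup_measures.append(tuple(MEASURES[mi] for mi in idxs))
        ci_ok[r] = all(bool(row[f"ci_{MEASURES[mi]}"]) for mi in idxs)

    q = bh_fdr(merged)
    df["p_merged"] = merged
    df["q"] = q
    df["support"] = support
    df["direction"] = direction
    df["passed_ci"] = ci_ok

    edges: list[EdgeRecord] = []
    for r in range(len(df)):
        if (
            support[r] >= min_support
            and np.isfinite(q[r])
            and q[r] < alpha
            and ci_ok[r]
        ):
            edges.append(
                EdgeRecord(
                    fungal_taxon=df.iloc[r]["fungal_taxon"],
                    bacterial_taxon=df.iloc[r]["bacterial_taxon"],
                    supporting_measures=sup_measures[r],
                    direction=str(direction[r]),
                    p_merged=float(merged[r]),
                    q=float(q[r]),
                    passed_ci=True,
                )
            )
    nodes: dict[str, str] = {}
    if inp is not None:
        nodes.update({t: "fungi" for t in inp.fungal_ids})
        nodes.update({t: "bacteria" for t in inp.bacterial_ids})
    else:
        for e in edges:
            nodes[e.fungal_taxon] = "fungi"
            nodes[e.bacterial_taxon] = "bacteria"
    return CoNetwork(
        nodes=nodes,
        edges=edges,
        stratum=stratum,
        n_candidates=int(np.isfinite(merged).sum()),
        candidates=df,
    )


# ---------------------------------------------------------------------------
# hubs and summaries
# ---------------------------------------------------------------------------

def find_hubs(network: CoNetwork, k: int = 4) -> list[str]:
    """Top-k nodes by degree; nodes tied with the k-th degree are included.

    Ordering within the list is by (degree, summed edge strength, ID).
    """
    deg = network.degree()
    if not deg:
        warnings.warn("empty network: no hubs", stacklevel=2)
        return []
    strength = network.strength()
    ordered = sorted(
        deg, key=lambda t: (-deg[t], -strength.get(t, 0.0), t)
    )
    if len(ordered) <= k:
        return ordered
    cutoff = deg[ordered[k - 1]]
    return [t for t in ordered if deg[t] >= cutoff]


def hub_union(networks: Iterable[CoNetwork], k: int = 4) -> list[str]:
    """De-duplicated union of per-network hub lists, in first-seen order."""
    seen: dict[str, None] = {}
    for net in networks:
        if not net.edges:
            continue
        for t in find_hubs(net, k):
            seen.setdefault(t, None)
    return list(seen)


def exclusion_fraction(network: CoNetwork) -> float:
    """Fraction of retained edges whose direction is mutual exclusion."""
    if not network.edges:
        raise ValueError("exclusion fraction undefined for an empty network")
    n_ex = sum(1 for e in network.edges if e.direction == EXCLUSION)
    return n_ex / len(network.edges)


def stratify_samples(
    meta: Sequence[SampleMetadata],
    sample_ids: Sequence[str],
) -> dict[str, list[str]]:
    """Sample subsets for the overall / bloat / no-bloat networks.

    The overall set is every aligned sample; the strata contain only
    grazing samples (baseline bloat status is NA) with the given label.
    """
    by_id = {m.sample_id: m for m in meta}
    out = {"overall": [s for s in sample_ids if s in by_id]}
    out["bloat"] = [
        s for s in out["overall"]
        if by_id[s].treatment is not Treatment.BASELINE
        and by_id[s].bloat is Bloat.B
    ]
    out["no-bloat"] = [
        s for s in out["overall"]
        if by_id[s].treatment is not Treatment.BASELINE
        and by_id[s].bloat is Bloat.NB
    ]
    return out
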