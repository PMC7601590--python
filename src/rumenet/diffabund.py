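"""Per-ASV blocked permutation ANOVA on CLR abundances.

Diet/bloat-status effects on each taxon's CLR abundance are tested with
an F statistic from the additive two-way fit (group + steer block
intercepts); the null distribution permutes group labels WITHIN each
steer block, which respects the repeated-measures structure of the
crossover without fitting a variance component.  P-values are corrected
across taxa by Benjamini-Hochberg and significant taxa get matched-pairs
Wilcoxon follow-up contrasts against the baseline diet (plus a rank-sum
comparison of bloat vs no-bloat within the alfalfa-sainfoin diet, whose
steer sets are disjoint so pairing is impossible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product as iter_product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sympy.utilities.iterables import multiset_permutations

from .diversity import pair_by_steer, wilcoxon_signed_rank
from .network import bh_fdr
from .preprocess import ClrMatrix, clr_transform, filter_prevalence, replace_zeros_bayesian
from .tables_io import Bloat, CountTable, SampleMetadata, Treatment

__all__ = [
    "DiffAbundResult",
    "perm_anova_blocked",
    "run_diffabund",
    "pairwise_followup",
    "diet_bloat_groups",
]


@dataclass
class DiffAbundResult:
    per_taxon: pd.DataFrame          # f_stat, p_perm, q, flagged per taxon
    group_means: pd.DataFrame        # taxon x group CLR means
    flagged: list[str]
    clr: ClrMatrix
    groups: pd.Series                # group label per sample
    blocks: pd.Series                # steer per sample


def diet_bloat_groups(meta: Sequence[SampleMetadata]) -> dict[str, str]:
    """Diet/bloat-status combination label per sample (baseline kept whole)."""
    out = {}
    for m in meta:
        if m.treatment is Treatment.BASELINE:
            out[m.sample_id] = "BASELINE"
        else:
            out[m.sample_id] = f"{m.treatment.value}-{m.bloat.value}"
    return out


def _block_basis(blocks: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the intercept + block-indicator column space."""
    levels = sorted(set(blocks))
    X = np.ones((blocks.size, 1))
    if len(levels) > 1:
        X = np.hstack(
            [X] + [(blocks == lev).astype(float)[:, None] for lev in levels[1:]]
        )
    q, _ = np.linalg.qr(X)
    return q


def _group_basis_given_block(
    groups: np.ndarray, qb: np.ndarray, rtol: float = 1e-10
) -> np.ndarray:
    """Orthonormal basis of the group design residualized on the block span."""
    levels = sorted(set(groups))
    G = np.stack([(groups == lev).astype(float) for lev in levels[1:]], axis=1)
    Gr = G - qb @ (qb.T @ G)
    u, s, _ = np.linalg.svd(Gr, full_matrices=False)
    rank = int(np.sum(s > rtol * max(s[0], 1.0))) if s.size else 0
    return u[:, :rank]


def _f_stats(
    V: np.ndarray, groups: np.ndarray, qb: np.ndarray
) -> tuple[np.ndarray, int, int]:
    """F per column of V for group effects given block intercepts."""
    Vr = V - qb @ (qb.T @ V)
    qg = _group_basis_given_block(groups, qb)
    df_g = qg.shape[1]
    if df_g == 0:
        raise ValueError("group design aliased with blocks (no testable df)")
    proj = qg.T @ Vr
    ss_g = (proj**2).sum(axis=0)
    ss_tot = (Vr**2).sum(axis=0)
    ss_res = ss_tot - ss_g
    df_res = V.shape[0] - qb.shape[1] - df_g
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    # numerical floor on the scale of the data, so block-perfect fits give
    # F = 0 rather than a 0/0 artefact
    tol = 1e-10 * np.maximum((V**2).sum(axis=0), 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_g / df_g) / (np.maximum(ss_res, 0.0) / df_res)
    f = np.where(ss_res <= tol, np.inf, f)
    f = np.where(ss_g <= tol, 0.0, f)
    return f, df_g, df_res


def _within_block_permutations(
    groups: np.ndarray, blocks: np.ndarray, rng: np.random.Generator, b: int
) -> list[np.ndarray]:
    """``b`` random permutations of the group labels within each block."""
    out = []
    block_idx = {lev: np.flatnonzero(blocks == lev) for lev in sorted(set(blocks))}
    for _ in range(b):
        g = groups.copy()
        for idx in block_idx.values():
            g[idx] = g[idx][rng.permutation(idx.size)]
        out.append(g)
    return out


def _all_within_block_permutations(
    groups: np.ndarray, blocks: np.ndarray, limit: int = 500_000
) -> list[np.ndarray]:
    """Every distinct within-block rearrangement of the group labels."""
    block_idx = [np.flatnonzero(blocks == lev) for lev in sorted(set(blocks))]
    per_block = [
        [np.asarray(p, dtype=groups.dtype) for p in
         multiset_permutations(list(groups[idx]))]
        for idx in block_idx
    ]
    total = int(np.prod([len(p) for p in per_block]))
    if total > limit:
        raise ValueError(f"{total} exhaustive permutations exceed limit {limit}")
    out = []
    for combo in iter_product(*per_block):
        g = groups.copy()
        for idx, vals in zip(block_idx, combo):
            g[idx] = vals
        out.append(g)
    return out


def perm_anova_blocked(
    values: Sequence[float],
    group: Sequence,
    block: Sequence,
    b: int = 4999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Permutation ANOVA of one CLR vector with steer as a blocking factor.

    Returns ``(F, p)`` where F comes from the additive group + block fit
    and p from permuting group labels within blocks:
    ``p = (1 + #{F* >= F}) / (B + 1)``, or the exact fraction over every
    within-block rearrangement when ``exhaustive=True``.
    """
    v = np.asarray(values, dtype=float)[:, None]
    groups = np.asarray([str(g) for g in group])
    blocks = np.asarray([str(s) for s in block])
    if not exhaustive and b < 199:
        raise ValueError("b must be >= 199")
    present = set(groups)
    if len(present) < 2:
        raise ValueError("need at least two groups")
    qb = _block_basis(blocks)
    f_obs, _, _ = _f_stats(v, groups, qb)
    f_obs = float(f_obs[0])
    if exhaustive:
        perms = _all_within_block_permutations(groups, blocks)
        count = 0
        for g in perms:
            f_star = float(_f_stats(v, g, qb)[0][0])
            if f_star >= f_obs - 1e-9 * max(1.0, abs(f_obs)):
                count += 1
        return f_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    exceed = 0
    for g in _within_block_permutations(groups, blocks, rng, b):
        f_star = float(_f_stats(v, g, qb)[0][0])
        if f_star >= f_obs - 1e-9 * max(1.0, abs(f_obs)):
            exceed += 1
    return f_obs, (1.0 + exceed) / (b + 1.0)


def run_diffabund(
    table: CountTable,
    meta: Sequence[SampleMetadata],
    min_prevalence: float = 0.10,
    b: int = 4999,
    seed: int = 0,
    alpha: float = 0.05,
) -> DiffAbundResult:
    """Prevalence filter, CLR transform, per-taxon blocked permutation ANOVA
    and BH correction across taxa.

    The group factor is the diet/bloat-status combination; the block
    factor is the steer.  All taxa share the same within-block label
    permutations, so the per-taxon tests are mutually consistent and the
    whole scan is a single pass per permutation.
    """
    by_id = {m.sample_id: m for m in meta}
    keep = [i for i, s in enumerate(table.sample_ids) if s in by_id]
    if len(keep) < table.n_samples:
        warnings.warn("samples without metadata were dropped", stacklevel=2)
    table = table.select_samples(keep)

    table = filter_prevalence(table, min_prevalence)
    comp = replace_zeros_bayesian(table)
    clr = clr_transform(comp)

    labels = diet_bloat_groups([by_id[s] for s in table.sample_ids])
    groups = np.asarray([labels[s] for s in table.sample_ids])
    blocks = np.asarray([by_id[s].steer_id for s in table.sample_ids])
    V = np.asarray(clr.values)

    qb = _block_basis(blocks)
    f_obs, _, _ = _f_stats(V, groups, qb)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(V.shape[1])
    for g in _within_block_permutations(groups, blocks, rng, b):
        f_star, _, _ = _f_stats(V, g, qb)
        exceed += f_star >= f_obs - 1e-9 * np.maximum(1.0, np.abs(f_obs))
    p = (1.0 + exceed) / (b + 1.0)
    q = bh_fdr(p)

    per_taxon = pd.DataFrame(
        {
            "taxon": clr.taxon_ids,
            "f_stat": f_obs,
            "p_perm": p,
            "q": q,
            "flagged": q < alpha,
        }
    ).set_index("taxon")

    gm = pd.DataFrame(V, index=clr.sample_ids, columns=clr.taxon_ids)
    gm["__group"] = groups
    group_means = gm.groupby("__group").mean().T

    return DiffAbundResult(
        per_taxon=per_taxon,
        group_means=group_means,
        flagged=[t for t, fl in per_taxon["flagged"].items() if fl],
        clr=clr,
        groups=pd.Series(groups, index=clr.sample_ids),
        blocks=pd.Series(blocks, index=clr.sample_ids),
    )


def pairwise_followup(
    result: DiffAbundResult,
    meta: Sequence[SampleMetadata],
    taxa: Optional[Sequence[str]] = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Follow-up contrasts for flagged taxa.

    Baseline vs each diet/bloat group uses the matched-pairs Wilcoxon
    signed-rank test (pairing by steer); bloat vs no-bloat within the
    alfalfa-sainfoin diet uses the Mann-Whitney rank-sum test because the
    two groups contain disjoint steers.  P-values are BH-corrected across
    taxa within each contrast.
    """
    taxa = list(taxa) if taxa is not None else list(result.flagged)
    by_id = {m.sample_id: m for m in meta}
    clr = result.clr
    V = pd.DataFrame(clr.values, index=clr.sample_ids, columns=clr.taxon_ids)
    groups = result.groups
    contrasts = [g for g in sorted(groups.unique()) if g != "BASELINE"]

    rows = []
    for contrast in contrasts:
        for taxon in taxa:
            vals = V[taxon]
            a = pair_by_steer(
                vals.to_dict(), meta,
                lambda m, c=contrast: groups.get(m.sample_id) == c,
            )
            b_ = pair_by_steer(
                vals.to_dict(), meta,
                lambda m: groups.get(m.sample_id) == "BASELINE",
            )
            common = set(a) & set(b_)
            stat = p = np.nan
            note = ""
            if len(common) < min_pairs:
                note = "insufficient pairs"
                warnings.warn(
                    f"contrast {contrast} vs BASELINE for {taxon}: "
                    f"{len(common)} effective pairs",
                    stacklevel=2,
                )
            else:
                try:
                    stat, p = wilcoxon_signed_rank(a, b_)
                except ValueError as err:
                    note = str(err)
            med = np.nan
            if common:
                med = float(np.median([a[k] - b_[k] for k in sorted(common)]))
            rows.append(
                {
                    "contrast": f"{contrast} vs BASELINE",
                    "taxon": taxon,
                    "statistic": stat,
                    "p": p,
                    "median_diff": med,
                    "note": note,
                }
            )

    # bloat vs no-bloat within AS (disjoint steers -> rank-sum)
    as_b = groups[groups == f"{Treatment.AS.value}-{Bloat.B.value}"].index
    as_nb = groups[groups == f"{Treatment.AS.value}-{Bloat.NB.value}"].index
    if len(as_b) >= 2 and len(as_nb) >= 2:
        for taxon in taxa:
            x, y = V.loc[as_b, taxon], V.loc[as_nb, taxon]
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(
                {
                    "contrast": "AS-B vs AS-NB",
                    "taxon": taxon,
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                    "median_diff": float(np.median(x) - np.median(y)),
                    "note": "rank-sum (disjoint steers)",
                }
            )

    out = pd.DataFrame(
        rows,
        columns=["contrast", "taxon", "statistic", "p", "median_diff", "note"],
    )
    if len(out):
        out["q"] = np.nan
        for contrast, idx in out.groupby("contrast").groups.items():
            out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"])
    return out
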