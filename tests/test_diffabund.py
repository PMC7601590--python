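"""Blocked permutation ANOVA, its exact small-sample null, and follow-ups."""

from itertools import permutations as iperm, product as iproduct

import numpy as np
import pandas as pd
import pytest

from rumenet.diffabund import (
    diet_bloat_groups,
    pairwise_followup,
    perm_anova_blocked,
    run_diffabund,
)
from rumenet.synthetic import SyntheticConfig, generate_dataset, null_dataset
from rumenet.tables_io import Bloat, SampleMetadata, Treatment


def _oracle_blocked_anova(values, groups, blocks):
    """Independent brute force: additive linear-model F via lstsq over every
    distinct within-block rearrangement of the group labels."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    blocks = np.asarray(blocks)

    def design(g):
        cols = [np.ones(len(g))]
        for lev in sorted(set(blocks))[1:]:
            cols.append((blocks == lev).astype(float))
        block_only = np.column_stack(cols)
        for lev in sorted(set(g))[1:]:
            cols.append((g == lev).astype(float))
        return block_only, np.column_stack(cols)

    def f_stat(g):
        xb, xf = design(g)
        rss_b = np.sum((values - xb @ np.linalg.lstsq(xb, values, rcond=None)[0]) ** 2)
        rss_f = np.sum((values - xf @ np.linalg.lstsq(xf, values, rcond=None)[0]) ** 2)
        df_g = np.linalg.matrix_rank(xf) - np.linalg.matrix_rank(xb)
        df_r = len(values) - np.linalg.matrix_rank(xf)
        if rss_f <= 1e-12 * max(rss_b, 1e-30):
            return 0.0 if rss_b - rss_f <= 1e-12 else np.inf
        return ((rss_b - rss_f) / df_g) / (rss_f / df_r)

    # enumerate distinct within-block label arrangements
    block_levels = sorted(set(blocks))
    per_block = []
    for lev in block_levels:
        idx = np.flatnonzero(blocks == lev)
        arrangements = {tuple(p) for p in iperm(tuple(groups[idx]))}
        per_block.append((idx, sorted(arrangements)))
    f_obs = f_stat(groups)
    count = total = 0
    for combo in iproduct(*[a for _, a in per_block]):
        g = groups.copy()
        for (idx, _), vals in zip(per_block, combo):
            g[idx] = vals
        total += 1
        if f_stat(g) >= f_obs - 1e-9:
            count += 1
    return f_obs, count / total


class TestPermAnovaBlocked:
    def test_identical_within_blocks_gives_f_zero_p_one(self):
        # same value for every group within each steer: no group signal
        values = [1.0, 1.0, 5.0, 5.0]
        groups = ["a", "b", "a", "b"]
        blocks = ["s1", "s1", "s2", "s2"]
        f, p = perm_anova_blocked(values, groups, blocks, exhaustive=True)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_reaches_symmetry_floor(self):
        """A huge planted shift attains the smallest achievable p: the
        within-block null keeps only the g! global relabelings tied with
        the observed assignment (2 of 2^6 arrangements here)."""
        rng = np.random.default_rng(0)
        blocks = np.repeat([f"s{i}" for i in range(6)], 2)
        groups = np.tile(["a", "b"], 6)
        values = np.where(groups == "b", 10.0, 0.0) + rng.normal(0, 0.01, 12)
        f, p = perm_anova_blocked(values, groups, blocks, exhaustive=True)
        assert p == pytest.approx(2 / 64)
        assert f > 1e4

    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(12):
            n_blocks = 3
            blocks = np.repeat([f"s{i}" for i in range(n_blocks)], 2)
            groups = np.tile(["a", "b"], n_blocks)
            values = rng.normal(size=2 * n_blocks)
            f, p = perm_anova_blocked(values, groups, blocks, exhaustive=True)
            f_o, p_o = _oracle_blocked_anova(values, groups, blocks)
            assert f == pytest.approx(f_o, rel=1e-9, abs=1e-9)
            assert p == pytest.approx(p_o, abs=1e-9)

    def test_single_block_equals_free_permutation_oneway(self):
        """With every sample in one block, the blocked test reduces to a
        free-permutation one-way ANOVA."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=8)
        groups = ["a", "a", "b", "b", "a", "b", "a", "b"]
        blocks = ["s1"] * 8
        f, p = perm_anova_blocked(values, groups, blocks, exhaustive=True)
        f_o, p_o = _oracle_blocked_anova(values, groups, blocks)
        assert f == pytest.approx(f_o, rel=1e-9, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        blocks = np.repeat([f"s{i}" for i in range(5)], 3)
        groups = np.tile(["a", "b", "c"], 5)
        values = rng.normal(size=15)
        r1 = perm_anova_blocked(values, groups, blocks, b=299, seed=7)
        r2 = perm_anova_blocked(values, groups, blocks, b=299, seed=7)
        assert r1 == r2


class TestRunDiffabund:
    def test_flags_planted_shift(self, small_dataset):
        """A strong artificial group shift on a few taxa is recovered."""
        cfg, (fungal, bacterial, meta, truth) = small_dataset
        table = fungal
        # plant a large count inflation for grazing samples on 3 taxa
        counts = table.counts.copy()
        grazing = [
            i for i, s in enumerate(table.sample_ids)
            if next(m for m in meta if m.sample_id == s).treatment
            is not Treatment.BASELINE
        ]
        for j in (0, 1, 2):
            counts[grazing, j] = counts[grazing, j] * 6 + 50
        from rumenet.tables_io import CountTable

        table2 = CountTable(table.sample_ids, table.taxon_ids, counts,
                            table.taxonomy)
        res = run_diffabund(table2, meta, min_prevalence=0.1, b=499, seed=0)
        flagged = set(res.flagged)
        assert {table.taxon_ids[0], table.taxon_ids[1]} & flagged

    def test_null_data_flags_almost_nothing(self):
        fracs = []
        for seed in (21, 22):
            cfg = SyntheticConfig(
                seed=seed, n_fungal_taxa=20, n_offtarget_fungi=0,
                n_bacterial_taxa=20, n_hubs=1, partners_per_hub=2,
                depth_fungal=(np.log(8000.0), 0.2),
                depth_bacterial=(np.log(8000.0), 0.2),
            )
            f, b, meta, truth = null_dataset(cfg)
            res = run_diffabund(f, meta, min_prevalence=0.1, b=199, seed=seed)
            fracs.append(len(res.flagged) / len(res.per_taxon))
        assert np.mean(fracs) <= 0.05

    def test_deterministic(self, small_dataset):
        cfg, (fungal, bacterial, meta, truth) = small_dataset
        a = run_diffabund(fungal, meta, b=199, seed=5).per_taxon
        b_ = run_diffabund(fungal, meta, b=199, seed=5).per_taxon
        pd.testing.assert_frame_equal(a, b_)


class TestPairwiseFollowup:
    def test_contrast_tables_and_bh_within_contrast(self, small_dataset):
        cfg, (fungal, bacterial, meta, truth) = small_dataset
        res = run_diffabund(fungal, meta, min_prevalence=0.1, b=199, seed=1)
        taxa = list(res.per_taxon.index[:4])
        out = pairwise_followup(res, meta, taxa=taxa)
        assert set(out["taxon"]) <= set(taxa)
        # BH within each contrast matches the step-up oracle
        for _, sub in out.groupby("contrast"):
            p = sub["p"].to_numpy(float)
            ok = np.isfinite(p)
            if ok.sum() < 2:
                continue
            from test_network import oracle_bh as _obh
            assert np.allclose(
                sub["q"].to_numpy(float)[ok], _obh(p[ok]), atol=1e-12
            )

    def test_groups_factor_construction(self, toy_meta):
        groups = diet_bloat_groups(toy_meta)
        assert groups == {"s1": "BASELINE", "s2": "PA-B", "s3": "PA-NB"}
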