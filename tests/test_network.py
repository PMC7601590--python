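"""Association measures, ReBoot null, bootstrap, Brown's merge, edge rules,
hub selection and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumenet import network as nw
from rumenet.network import (
    COPRESENCE,
    EXCLUSION,
    MEASURES,
    CoNetwork,
    MeasureScore,
    association_score,
    bh_fdr,
    bootstrap_distribution,
    browns_merge,
    exclusion_fraction,
    find_hubs,
    hub_union,
    measure_pvalue,
    reboot_null,
)
from rumenet.tables_io import EdgeRecord


# --------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation
# --------------------------------------------------------------------------

def _midrank(v):
    v = np.asarray(v, dtype=float)
    out = np.empty(len(v))
    for i, x in enumerate(v):
        out[i] = np.sum(v < x) + (np.sum(v == x) + 1) / 2.0
    return out


def oracle_spearman(x, y):
    rx, ry = _midrank(x), _midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())


def oracle_kendall_b(x, y):
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[i] - x[j], y[i] - y[j]
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a * b > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))


def _tie_term(v):
    vals, counts = np.unique(v, return_counts=True)
    return sum(t * (t - 1) / 2 for t in counts)


def oracle_bray_curtis(x, y):
    return sum(abs(a - b) for a, b in zip(x, y)) / sum(
        a + b for a, b in zip(x, y)
    )


def oracle_kld(x, y, eps=1e-6):
    p = [(v + eps) for v in x]
    q = [(v + eps) for v in y]
    p = [v / sum(p) for v in p]
    q = [v / sum(q) for v in q]
    d_pq = sum(a * np.log(a / b) for a, b in zip(p, q))
    d_qp = sum(b * np.log(b / a) for a, b in zip(p, q))
    return 0.5 * (d_pq + d_qp)


def oracle_bh(pvals):
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        prev = min(prev, p[idx] * m / rank_from_top)
        q[idx] = prev
    return q


class TestAssociationScores:
    def test_identity_pair(self):
        x = np.array([0.1, 0.3, 0.2, 0.4, 0.05])
        assert association_score(x, x, "SPEARMAN") == pytest.approx(1.0)
        assert association_score(x, x, "KENDALL") == pytest.approx(1.0)
        assert association_score(x, x, "BRAY_CURTIS") == pytest.approx(0.0)
        assert association_score(x, x, "KLD") == pytest.approx(0.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert association_score(x, x[::-1], "SPEARMAN") == pytest.approx(-1.0)

    def test_zero_variance_gives_nan(self):
        x = np.full(6, 0.2)
        y = np.array([0.1, 0.2, 0.3, 0.15, 0.05, 0.2])
        assert np.isnan(association_score(x, y, "SPEARMAN"))
        assert np.isnan(association_score(x, y, "KENDALL"))

    @pytest.mark.parametrize("measure,oracle", [
        ("SPEARMAN", oracle_spearman),
        ("KENDALL", oracle_kendall_b),
        ("BRAY_CURTIS", oracle_bray_curtis),
        ("KLD", oracle_kld),
    ])
    def test_matches_bruteforce_on_random_pairs(self, measure, oracle):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 8, size=20) / 37.0
            y = rng.integers(0, 8, size=20) / 41.0
            got = association_score(x, y, measure)
            if np.isnan(got):
                continue
            assert got == pytest.approx(oracle(x, y), abs=1e-12)


class TestRebootNull:
    def test_independent_pair_null_centred_at_zero(self):
        rng = np.random.default_rng(1)
        x = rng.random(30) * 0.01
        y = rng.random(30) * 0.01
        mu, sd = reboot_null((x, y), None, "SPEARMAN", b_perm=500, seed=2)
        assert abs(mu) <= 3 * sd / np.sqrt(500) + 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(12) * 0.1, rng.random(12) * 0.1
        a = reboot_null((x, y), None, "KENDALL", b_perm=120, seed=9)
        b = reboot_null((x, y), None, "KENDALL", b_perm=120, seed=9)
        assert a == b

    def test_renormalization_noop_for_negligible_pair(self):
        """When the pair is a negligible fraction of each sample the
        renormalized and plain nulls agree."""
        rng = np.random.default_rng(4)
        x = rng.random(25) * 1e-4
        y = rng.random(25) * 1e-4
        mu_r, _ = reboot_null((x, y), np.ones(25), "SPEARMAN",
                              b_perm=300, seed=5, renormalize=True)
        mu_p, sd_p = reboot_null((x, y), np.ones(25), "SPEARMAN",
                                 b_perm=300, seed=5, renormalize=False)
        assert mu_r == pytest.approx(mu_p, abs=5 * sd_p / np.sqrt(300) + 1e-6)

    def test_small_b_perm_warns(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(10), rng.random(10)
        with pytest.warns(UserWarning, match="unstable"):
            reboot_null((x, y), None, "BRAY_CURTIS", b_perm=50, seed=0)


class TestBootstrap:
    def test_perfect_correlation_tight(self):
        x = np.linspace(0.01, 0.2, 20)
        mu, sd, ci = bootstrap_distribution((x, 2 * x), "SPEARMAN",
                                            b_boot=200, seed=0)
        assert mu == pytest.approx(1.0)
        assert sd < 1e-9
        assert ci == (pytest.approx(1.0), pytest.approx(1.0))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(15), rng.random(15)
        a = bootstrap_distribution((x, y), "KLD", b_boot=100, seed=3)
        b = bootstrap_distribution((x, y), "KLD", b_boot=100, seed=3)
        assert a == b

    def test_ci_contains_observed_for_most_pairs(self):
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(40):
            x, y = rng.random(25), rng.random(25)
            obs = association_score(x, y, "SPEARMAN")
            _, _, (lo, hi) = bootstrap_distribution(
                (x, y), "SPEARMAN", b_boot=300, seed=int(rng.integers(1e6))
            )
            total += 1
            hits += lo - 1e-9 <= obs <= hi + 1e-9
        assert hits / total >= 0.94

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="at least 8"):
            bootstrap_distribution(
                (np.ones(5), np.ones(5)), "KLD", b_boot=10, seed=0
            )


class TestMeasurePvalue:
    def _score(self, **kw):
        base = dict(measure="SPEARMAN", observed=0.5, null_mean=0.0,
                    null_sd=0.1, boot_mean=0.5, boot_sd=0.1,
                    boot_ci=(0.3, 0.7))
        base.update(kw)
        return MeasureScore(**base)

    def test_boot_mean_equals_null_mean_gives_p_one(self):
        s = self._score(boot_mean=0.0, observed=0.0)
        assert measure_pvalue(s) == pytest.approx(1.0)
        s = self._score(boot_mean=0.0, observed=0.0)
        assert measure_pvalue(s, two_sided=False) == pytest.approx(0.5)

    def test_196_sigma_gives_p_005(self):
        s = self._score(null_mean=1.96 * 0.1, boot_mean=0.0, observed=-0.2)
        assert measure_pvalue(s) == pytest.approx(0.05, rel=1e-3)
        s = self._score(null_mean=1.96 * 0.1, boot_mean=0.0, observed=-0.2)
        assert measure_pvalue(s, two_sided=False) == pytest.approx(0.025, rel=1e-3)

    def test_symmetric_in_sign_of_z(self):
        p1 = measure_pvalue(self._score(null_mean=0.3, boot_mean=0.0))
        p2 = measure_pvalue(self._score(null_mean=-0.3, boot_mean=0.0))
        assert p1 == pytest.approx(p2)

    def test_direction_rules(self):
        assert self._dir(measure="SPEARMAN", observed=-0.4) == EXCLUSION
        assert self._dir(measure="SPEARMAN", observed=0.4) == COPRESENCE
        assert self._dir(measure="BRAY_CURTIS", observed=0.9,
                         null_mean=0.5) == EXCLUSION
        assert self._dir(measure="KLD", observed=0.1,
                         null_mean=0.5) == COPRESENCE

    def _dir(self, **kw):
        s = self._score(**kw)
        measure_pvalue(s)
        return s.direction

    def test_zero_boot_sd_drops_measure(self):
        s = self._score(boot_sd=0.0)
        assert np.isnan(measure_pvalue(s))


class TestBrownsMerge:
    def test_zero_cov_reduces_to_fisher(self):
        p = browns_merge([0.05, 0.05], np.zeros((2, 2)))
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert p == pytest.approx(stats.chi2.sf(x, 4), abs=1e-10)
        assert p == pytest.approx(0.01747, abs=5e-5)

    def test_all_ones_merge_to_one(self):
        assert browns_merge([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_perfect_dependence_collapses_to_single_p(self):
        for p0 in (0.3, 0.04, 1e-4):
            cov = np.full((2, 2), 4.0)
            assert browns_merge([p0, p0], cov) == pytest.approx(p0, rel=1e-10)

    def test_out_of_range_cov_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            browns_merge([0.1, 0.2], np.array([[4.0, 9.0], [9.0, 4.0]]))


class TestBhFdr:
    def test_stepup_toy(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.40])
        assert q == pytest.approx([0.04, 0.04, 0.05333333, 0.40], abs=1e-8)

    def test_matches_oracle_and_idempotent(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            p = rng.random(rng.integers(2, 25))
            q = bh_fdr(p)
            assert np.allclose(q, oracle_bh(p), atol=1e-12)
            assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)  # monotone

    def test_nan_safe(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


def _toy_candidates():
    """Three candidate pairs: one strong exclusion, one strong copresence,
    one null."""
    rows = []
    for name, p_strong, direction in [
        ("good_neg", 1e-6, EXCLUSION),
        ("good_pos", 1e-5, COPRESENCE),
        ("null", 0.8, COPRESENCE),
    ]:
        row = {"fungal_taxon": f"F_{name}", "bacterial_taxon": f"B_{name}"}
        for m in MEASURES:
            row[f"p_{m}"] = p_strong
            row[f"dir_{m}"] = direction
            row[f"ci_{m}"] = True
            row[f"obs_{m}"] = 0.5
        rows.append(row)
    return pd.DataFrame(rows)


class TestBuildNetwork:
    def test_retains_strong_edges_with_directions(self):
        net = nw.build_network(_toy_candidates(), alpha=0.05, min_support=3)
        by_pair = {(e.fungal_taxon, e.bacterial_taxon): e for e in net.edges}
        assert ("F_good_neg", "B_good_neg") in by_pair
        assert by_pair["F_good_neg", "B_good_neg"].direction == EXCLUSION
        assert ("F_null", "B_null") not in by_pair

    def test_monotone_in_min_support_and_alpha(self):
        cand = _toy_candidates()
        e3 = {(e.fungal_taxon, e.bacterial_taxon)
              for e in nw.build_network(cand, min_support=3).edges}
        e4 = {(e.fungal_taxon, e.bacterial_taxon)
              for e in nw.build_network(cand, min_support=4).edges}
        assert e4 <= e3
        e_small_alpha = {
            (e.fungal_taxon, e.bacterial_taxon)
            for e in nw.build_network(cand, alpha=1e-8).edges
        }
        assert e_small_alpha <= e3

    def test_ci_failure_blocks_edge(self):
        cand = _toy_candidates()
        for m in MEASURES:
            cand.loc[0, f"ci_{m}"] = False
        net = nw.build_network(cand, min_support=3)
        assert ("F_good_neg", "B_good_neg") not in {
            (e.fungal_taxon, e.bacterial_taxon) for e in net.edges
        }

    def test_empty_candidates_give_empty_network(self):
        cand = _toy_candidates().iloc[:0]
        net = nw.build_network(cand)
        assert net.edges == []


def _edge(f, b, direction=EXCLUSION, p=1e-4):
    return EdgeRecord(f, b, ("SPEARMAN", "KENDALL", "KLD"), direction, p,
                      p * 2, True)


class TestHubsAndSummaries:
    def test_star_graph_center_is_top_hub(self):
        net = CoNetwork(
            nodes={}, edges=[_edge("F1", f"B{i}") for i in range(5)]
        )
        assert find_hubs(net, k=1) == ["F1"]

    def test_ties_at_boundary_are_reported(self):
        edges = [_edge(f"F{i}", f"B{i}") for i in range(6)]
        net = CoNetwork(nodes={}, edges=edges)
        hubs = find_hubs(net, k=4)
        assert len(hubs) == 12  # every node has degree 1: all tied

    def test_hub_union_dedupes(self):
        n1 = CoNetwork(nodes={}, edges=[_edge("F1", f"B{i}") for i in range(3)])
        n2 = CoNetwork(nodes={}, edges=[_edge("F1", f"C{i}") for i in range(3)])
        union = hub_union([n1, n2], k=1)
        assert union == ["F1"]

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="no hubs"):
            assert find_hubs(CoNetwork(nodes={}, edges=[])) == []

    def test_exclusion_fraction(self):
        edges = [_edge("F1", "B1"), _edge("F2", "B2"),
                 _edge("F3", "B3", COPRESENCE), _edge("F4", "B4", COPRESENCE)]
        assert exclusion_fraction(CoNetwork(nodes={}, edges=edges)) == 0.5
        all_neg = CoNetwork(nodes={}, edges=edges[:2])
        assert exclusion_fraction(all_neg) == 1.0
        with pytest.raises(ValueError):
            exclusion_fraction(CoNetwork(nodes={}, edges=[]))


class TestEngineAgainstPerPairReference:
    """The vectorized engine must agree with the single-pair operations."""

    def test_observed_scores_match_reference(self, small_dataset):
        from rumenet import preprocess as pp

        cfg, (fungal, bacterial, meta, truth) = small_dataset
        ff = pp.filter_taxonomy(fungal, "Neocallimastigomycota")
        inp = nw.prepare_network_input(ff, bacterial, min_prevalence=0.5)
        obs = nw._observed_scores(inp)
        F, B = inp.fungal_block(), inp.bacterial_block()
        rng = np.random.default_rng(0)
        for _ in range(25):
            i = int(rng.integers(F.shape[1]))
            j = int(rng.integers(B.shape[1]))
            for m in MEASURES:
                ref = association_score(F[:, i], B[:, j], m)
                got = obs[m][i, j]
                if np.isnan(ref):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(ref, abs=1e-9), m

    def test_null_stats_match_reference_within_mc_error(self, small_dataset):
        from rumenet import preprocess as pp

        cfg, (fungal, bacterial, meta, truth) = small_dataset
        ff = pp.filter_taxonomy(fungal, "Neocallimastigomycota")
        inp = nw.prepare_network_input(ff, bacterial, min_prevalence=0.5)
        nulls = nw._null_stats(inp, 400, np.random.default_rng(1))
        F, B = inp.fungal_block(), inp.bacterial_block()
        for (i, j) in [(0, 0), (2, 5)]:
            for m in MEASURES:
                mu_ref, sd_ref = reboot_null(
                    (F[:, i], B[:, j]),
                    inp.rel, m, b_perm=400, seed=77,
                )
                mu = nulls[m][0][i, j]
                tol = 5 * sd_ref / np.sqrt(400) + 1e-9
                assert mu == pytest.approx(mu_ref, abs=tol), m
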