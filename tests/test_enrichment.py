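import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mdiva import (
    DegenerateSetError,
    GeneSet,
    bh_adjust,
    edge_annotation_counts,
    group_walks,
    gsva_genes,
    ks_walk,
    merge_gene_sets,
    rank_edges,
    residual_max_pvalue,
    residual_quadrant,
    sample_walks,
    walk_max_pvalue,
    walk_percentiles,
)


def signed_ks_oracle(in_pos, out_pos, n_positions):
    """Independent signed two-sample KS: ECDF difference via searchsorted."""
    in_pos = np.sort(in_pos)
    out_pos = np.sort(out_pos)
    w = np.arange(1, n_positions + 1)
    diff = np.searchsorted(in_pos, w, side="right") / len(in_pos) - np.searchsorted(
        out_pos, w, side="right"
    ) / len(out_pos)
    return diff[np.argmax(np.abs(diff))]


class TestRankEdges:
    def test_descending_magnitude_order(self):
        order = rank_edges(np.array([1.0, 5.0, 3.0]), np.zeros(3), ["e1", "e2", "e3"])
        assert list(order) == [1, 2, 0]

    def test_tau_zero_falls_back_to_tie_break(self):
        order = rank_edges(
            np.array([9.0, 1.0, 5.0]), np.array([3.0, 2.0, 1.0]), ["a", "b", "c"], tau=0.0
        )
        assert list(order) == [2, 1, 0]  # delta mass ascending

    def test_deterministic_with_duplicates(self):
        u = np.array([2.0, 2.0, 2.0, 1.0])
        deltas = np.array([5.0, 5.0, 1.0, 9.0])
        ids = ["b", "a", "c", "d"]
        o1 = rank_edges(u, deltas, ids)
        o2 = rank_edges(u.copy(), deltas.copy(), list(ids))
        assert list(o1) == list(o2) == [2, 1, 0, 3]


class TestKsWalk:
    def test_worked_example(self):
        wp = ks_walk(np.array([4.0, 3.0, 2.0, 1.0]), np.array([1, 0, 1, 0]), tau=1.0)
        np.testing.assert_allclose(wp.values, [2 / 3, 1 / 6, 1 / 2, 0.0], atol=5e-5)
        assert wp.es == pytest.approx(0.6667, abs=5e-5)

    def test_terminates_at_zero_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            r = int(rng.integers(3, 60))
            u = rng.lognormal(0, 1, r)
            c = rng.integers(0, 3, r)
            if c.sum() == 0 or (c == 0).sum() == 0:
                continue
            wp = ks_walk(np.sort(u)[::-1], c, tau=float(rng.uniform(0, 2)))
            assert abs(wp.values[-1]) < 1e-12
            assert np.max(np.abs(wp.values)) <= 1.0 + 1e-12
            assert wp.es == wp.values[np.argmax(np.abs(wp.values))]

    def test_classical_ks_limit_tau_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            r = int(rng.integers(6, 80))
            c = (rng.random(r) < 0.3).astype(int)
            if c.sum() == 0 or (c == 0).sum() == 0:
                continue
            u = rng.lognormal(0, 1, r)
            wp = ks_walk(u, c, tau=0.0)
            pos = np.arange(1, r + 1)
            expected = signed_ks_oracle(pos[c == 1], pos[c == 0], r)
            assert wp.es == pytest.approx(expected, abs=1e-12)
            d_scipy = stats.ks_2samp(pos[c == 1], pos[c == 0]).statistic
            assert abs(wp.es) == pytest.approx(d_scipy, abs=1e-12)

    def test_degenerate_sets_raise(self):
        with pytest.raises(DegenerateSetError):
            ks_walk(np.array([2.0, 1.0]), np.array([0, 0]))
        with pytest.raises(DegenerateSetError):
            ks_walk(np.array([2.0, 1.0]), np.array([1, 1]))

    def test_scale_invariance_of_sample_column(self, study):
        bundle, net, U = study
        gs = bundle.gene_sets[0]
        c = edge_annotation_counts(net, gs.members)
        if c.sum() == 0:
            pytest.skip("set has no annotated edges in this realization")
        deltas = net.edge_delta_masses()
        walks1 = sample_walks(U, {gs.set_id: c}, deltas, tau=1.0)
        walks2 = sample_walks(U * 37.5, {gs.set_id: c}, deltas, tau=1.0)
        for s in U.columns:
            np.testing.assert_allclose(
                walks1[gs.set_id][s].values, walks2[gs.set_id][s].values, atol=1e-12
            )


class TestPercentilesAndGroups:
    def test_two_sets_mean_rank(self):
        pct = walk_percentiles({"a": np.array([0.5]), "b": np.array([-0.5])})
        assert pct["a"][0] == pytest.approx(75.0)
        assert pct["b"][0] == pytest.approx(25.0)

    def test_total_tie_gives_50(self):
        pct = walk_percentiles({"a": np.array([0.3, 0.0]), "b": np.array([0.3, 0.0])})
        np.testing.assert_allclose(pct["a"], [50.0, 50.0])
        np.testing.assert_allclose(pct["b"], [50.0, 50.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        walks = {f"s{i}": rng.normal(size=20) for i in range(6)}
        before = walk_percentiles(walks)
        after = walk_percentiles({k: np.exp(3 * v) for k, v in walks.items()})
        for k in walks:
            np.testing.assert_allclose(before[k], after[k])

    def test_single_set_degenerates_to_50(self):
        pct = walk_percentiles({"only": np.array([0.1, -0.2])})
        np.testing.assert_allclose(pct["only"], [50.0, 50.0])

    def test_group_mean_walks(self):
        v = np.array([0.1, 0.2, 0.0])
        walks = {"s1": v, "s2": -v, "s3": v}
        groups = group_walks(walks, {"s1": "A", "s2": "A", "s3": "B"})
        np.testing.assert_allclose(groups["A"], np.zeros(3), atol=1e-15)
        np.testing.assert_allclose(groups["B"], v)

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            group_walks({"s1": np.zeros(2)}, {"s9": "A"})


class TestResidualQuadrant:
    def test_bloom_dominant_positive_is_quadrant_1(self):
        bloom = np.array([0.1, 0.4, 0.0])
        pre = np.array([0.05, 0.1, 0.0])
        rw = residual_quadrant(bloom, pre)
        assert rw.quadrant == 1
        assert rw.max_deviation == pytest.approx(0.4)

    def test_bloom_dominant_negative_is_quadrant_3(self):
        rw = residual_quadrant(np.array([-0.1, -0.4]), np.array([-0.05, -0.2]))
        assert rw.quadrant == 3

    def test_identical_walks_no_quadrant(self):
        v = np.array([0.3, -0.2, 0.0])
        rw = residual_quadrant(v, v.copy())
        np.testing.assert_allclose(rw.residual, 0.0)
        assert rw.quadrant is None

    def test_quadrant_2_when_pre_exceeds_positive_bloom(self):
        rw = residual_quadrant(np.array([0.3, 0.1]), np.array([0.1, 0.3]))
        # dominant deviation is bloom's 0.3 at position 0; residual +0.2 -> Q1
        assert rw.quadrant == 1
        rw2 = residual_quadrant(np.array([0.3, 0.0]), np.array([0.5, 0.0]))
        # pre dominates: axis 1 flips sign of pre's peak (-0.5), residual -0.2 -> Q3
        assert rw2.quadrant == 3

    def test_exact_antisymmetry_on_random_walks(self):
        rng = np.random.default_rng(4)
        mapping = {1: 3, 2: 4, 3: 1, 4: 2, None: None}
        for _ in range(200):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            fwd = residual_quadrant(a, b)
            rev = residual_quadrant(b, a)
            np.testing.assert_allclose(fwd.residual, -rev.residual)
            assert rev.quadrant == mapping[fwd.quadrant]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            residual_quadrant(np.zeros(3), np.zeros(4))


class TestMaxDeviationPvalues:
    def test_no_deviation_gives_p_one_both_methods(self):
        from mdiva.enrichment import _analytic_kolmogorov_p

        # a walk with zero maximum deviation has p = 1 analytically
        assert _analytic_kolmogorov_p(0.0, 10, 20) == 1.0
        # and p = 1 under permutation when every relabelling reaches the
        # observed maximum (two positions: both assignments give |max| = 1)
        _, p = walk_max_pvalue(np.ones(2), np.array([1, 0]), np.zeros(2),
                               ["a", "b"], tau=0.0, n_perm=99, seed=0)
        assert p == 1.0

    def test_concentrated_set_is_significant(self):
        rng = np.random.default_rng(6)
        r = 200
        u = np.sort(rng.lognormal(0, 1, r))[::-1]
        c = np.zeros(r, dtype=int)
        c[:20] = 1  # all in-set edges at the top of the ranking
        _, p = walk_max_pvalue(u, c, np.zeros(r), [f"e{i}" for i in range(r)],
                               n_perm=199, seed=1)
        assert p < 0.01

    def test_residual_pvalue_antisymmetric_quadrants(self, study):
        bundle, net, U = study
        deltas = net.edge_delta_masses()
        pw = sorted(bundle.ground_truth.affected_pathways)[0]
        gs = next(g for g in bundle.gene_sets if g.set_id == pw)
        c = edge_annotation_counts(net, gs.members)
        fwd = residual_max_pvalue(U, c, deltas, bundle.grouping, "bloom", "pre_bloom",
                                  n_perm=99, seed=3)
        rev = residual_max_pvalue(U, c, deltas, bundle.grouping, "pre_bloom", "bloom",
                                  n_perm=99, seed=3)
        np.testing.assert_allclose(fwd.residual, -rev.residual)
        assert {fwd.quadrant, rev.quadrant} in ({1, 3}, {2, 4})
        assert fwd.p_value == rev.p_value  # same permutations, |residual| identical


class TestGsvaGenes:
    @staticmethod
    def _planted_expr(seed, n_genes=60, up=frozenset(range(12))):
        rng = np.random.default_rng(seed)
        samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
        base = rng.lognormal(3, 0.6, size=(n_genes, 8))
        genes = [f"g{i}" for i in range(n_genes)]
        expr = pd.DataFrame(base, index=genes, columns=samples)
        expr.iloc[sorted(up), :4] *= 2.0
        grouping = {s: ("A" if s.startswith("A") else "B") for s in samples}
        gene_set = GeneSet("up_set", frozenset(genes[i] for i in up))
        return expr, gene_set, grouping

    def test_planted_up_set_positive_difference(self):
        hits = 0
        for seed in range(20):
            expr, gs, grouping = self._planted_expr(seed)
            table = gsva_genes(expr, [gs], grouping=grouping, group_a="A", group_b="B")
            hits += table.difference.loc["up_set"] > 0
        assert hits >= 19

    def test_label_swap_negates_difference(self):
        expr, gs, grouping = self._planted_expr(0)
        t1 = gsva_genes(expr, [gs], grouping=grouping, group_a="A", group_b="B")
        t2 = gsva_genes(expr, [gs], grouping=grouping, group_a="B", group_b="A")
        assert t1.difference.loc["up_set"] == pytest.approx(-t2.difference.loc["up_set"])

    def test_complementary_sets_anticorrelated(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(
            rng.lognormal(2, 1, size=(30, 10)),
            index=genes,
            columns=[f"s{i}" for i in range(10)],
        )
        half = frozenset(genes[:15])
        other = frozenset(genes[15:])
        table = gsva_genes(expr, [GeneSet("A", half), GeneSet("B", other)])
        r = np.corrcoef(table.es.loc["A"], table.es.loc["B"])[0, 1]
        assert r < 0

    def test_degenerate_set_skipped(self):
        expr, _, _ = self._planted_expr(0)
        covers_all = GeneSet("all", frozenset(expr.index))
        table = gsva_genes(expr, [covers_all])
        assert table.skipped == ["all"]


class TestMergeGeneSets:
    def test_disjoint_union(self):
        sets = [GeneSet("p1", frozenset("abc")), GeneSet("p2", frozenset("defg"))]
        merged = merge_gene_sets(sets, {"p1": "c1", "p2": "c1"})
        assert len(merged) == 1 and len(merged[0].members) == 7

    def test_overlapping_union(self):
        sets = [GeneSet("p1", frozenset("ab")), GeneSet("p2", frozenset("bc"))]
        merged = merge_gene_sets(sets, {"p1": "c", "p2": "c"})
        assert merged[0].members == frozenset("abc")

    def test_identity_map_is_noop(self):
        sets = [GeneSet("p1", frozenset("ab")), GeneSet("p2", frozenset("cd"))]
        merged = merge_gene_sets(sets, {"p1": "p1", "p2": "p2"})
        assert {m.set_id: m.members for m in merged} == {
            "p1": frozenset("ab"), "p2": frozenset("cd")
        }

    def test_missing_pathway_kept_as_own_class(self):
        sets = [GeneSet("p1", frozenset("ab")), GeneSet("orphan", frozenset("xy"))]
        merged = merge_gene_sets(sets, {"p1": "c1"})
        assert {m.set_id for m in merged} == {"c1", "orphan"}


def test_bh_adjust_monotone_and_bounded():
    p = [0.001, 0.01, 0.04, 0.2, 0.9]
    q = bh_adjust(p)
    assert (q >= p).all() and (q <= 1.0).all()
    assert list(q) == sorted(q)
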