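import numpy as np
import pytest
from scipy import stats

from drivescan import (
    RankedList,
    analyze_collection,
    enrichment_score,
    fdr_across_sets,
    intersect_leading_edges,
    permutation_null,
)
from drivescan.errors import ValidationError
from drivescan.formats import GeneSet, GeneSetCollection
from drivescan.gsea import _es_from_positions

from conftest import brute_force_running_sum


def _random_instance(rng, n_max=50):
    n = int(rng.integers(5, n_max + 1))
    genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
    metrics = np.sort(rng.normal(size=n))[::-1]
    metrics += np.linspace(0.001, 0, n)  # avoid exact ties
    size = int(rng.integers(1, max(2, n // 2)))
    members = rng.choice(genes, size=size, replace=False)
    return RankedList(genes, metrics), members


class TestRankedList:
    def test_sorted_descending_with_lexicographic_ties(self):
        ranked = RankedList(np.array(["b", "a", "c"], dtype=object),
                            np.array([1.0, 1.0, 2.0]))
        assert list(ranked.genes) == ["c", "a", "b"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValidationError):
            RankedList(np.array(["a", "a"], dtype=object), np.array([1.0, 2.0]))

    def test_from_correlations_uses_common_universe(self, corr_tables):
        ranked = RankedList.from_correlations(corr_tables)
        assert len(ranked) > 0
        assert ranked.metrics[0] >= ranked.metrics[-1]


class TestEnrichmentScore:
    def test_hand_computed_running_sum(self):
        ranked = RankedList(np.array(list("abcde"), dtype=object),
                            np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        es, running, leading = enrichment_score(ranked, ("a", "c"), w=1.0)
        # N_R = 5 + 3 = 8; misses decrement 1/3
        assert running == pytest.approx([0.625, 0.625 - 1/3, 2/3, 1/3, 0.0])
        assert es == pytest.approx(2/3)
        assert leading == ["a", "c"]

    def test_single_member_extremes(self):
        ranked = RankedList(np.array(list("abcd"), dtype=object),
                            np.array([4.0, 3.0, 2.0, 1.0]))
        es_top, _, le_top = enrichment_score(ranked, ("a",), w=1.0)
        assert es_top == pytest.approx(1.0)
        assert le_top == ["a"]
        es_bot, _, _ = enrichment_score(ranked, ("d",), w=1.0)
        assert es_bot == pytest.approx(-1.0)

    def test_running_sum_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ranked, members = _random_instance(rng)
            _, running, _ = enrichment_score(ranked, members, w=1.0)
            assert abs(running[-1]) < 1e-9

    def test_matches_brute_force_prefix_recomputation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            ranked, members = _random_instance(rng)
            for w in (0.0, 1.0):
                es, running, _ = enrichment_score(ranked, members, w=w)
                brute = brute_force_running_sum(ranked.genes, ranked.metrics,
                                                members, w)
                assert running == pytest.approx(brute, abs=1e-12)
                assert abs(es) == pytest.approx(np.max(np.abs(brute)), abs=1e-12)

    def test_w0_equals_classical_ks_statistic(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            ranked, members = _random_instance(rng)
            es, _, _ = enrichment_score(ranked, members, w=0.0)
            pos = ranked.positions(members)
            miss = np.setdiff1d(np.arange(len(ranked)), pos)
            ks = stats.ks_2samp(pos, miss).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_scale_invariance_of_metrics(self):
        rng = np.random.default_rng(3)
        ranked, members = _random_instance(rng)
        es1, _, _ = enrichment_score(ranked, members, w=1.0)
        scaled = RankedList(ranked.genes.copy(), ranked.metrics * 7.3)
        es2, _, _ = enrichment_score(scaled, members, w=1.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_fast_position_path_matches_full_running_sum(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            ranked, members = _random_instance(rng)
            es, running, _ = enrichment_score(ranked, members, w=1.0)
            pos = ranked.positions(members)[None, :]
            abs_w = np.abs(ranked.metrics)
            es_fast = _es_from_positions(abs_w, pos, len(ranked))[0]
            assert abs(es_fast) == pytest.approx(abs(es), abs=1e-12)
            # sign must agree except on a +/- magnitude tie at float precision
            if abs(running.max() + running.min()) > 1e-9:
                assert np.sign(es_fast) == np.sign(es)

    def test_no_member_in_universe_fatal(self):
        ranked = RankedList(np.array(["a", "b"], dtype=object), np.array([2.0, 1.0]))
        with pytest.raises(ValidationError):
            enrichment_score(ranked, ("zz",))

    def test_all_zero_hit_metrics_degenerate(self):
        ranked = RankedList(np.array(["a", "b", "c"], dtype=object),
                            np.array([1.0, 0.0, -1.0]))
        with pytest.raises(ValidationError, match="degenerate"):
            enrichment_score(ranked, ("b",), w=1.0)


class TestPermutationNull:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        ranked, members = _random_instance(rng, n_max=40)
        gs = GeneSet("S", "d", tuple(members))
        r1 = permutation_null(ranked, gs, n_perm=200, seed=42)
        r2 = permutation_null(ranked, gs, n_perm=200, seed=42)
        assert r1.nes == r2.nes and r1.p_perm == r2.p_perm
        assert np.array_equal(r1.null_es, r2.null_es)

    def test_planted_top_set_reaches_minimum_p(self):
        n = 500
        genes = np.array([f"g{i}" for i in range(n)], dtype=object)
        metrics = np.linspace(3, -3, n)
        ranked = RankedList(genes, metrics)
        gs = GeneSet("TOP", "planted", tuple(genes[:25]))
        res = permutation_null(ranked, gs, n_perm=1000, seed=0)
        # no same-sign permutation reaches the observed ES: minimum attainable
        n_same = int((res.null_es > 0).sum())
        assert res.p_perm == pytest.approx(1 / (n_same + 1))
        assert res.p_perm < 0.01
        assert res.nes > 1.5

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(6)
        n = 150
        genes = np.array([f"g{i}" for i in range(n)], dtype=object)
        rejections = 0
        n_trials = 300
        for _ in range(n_trials):
            metrics = np.sort(rng.normal(size=n))[::-1]
            ranked = RankedList(genes, metrics)
            members = tuple(rng.choice(genes, size=12, replace=False))
            res = permutation_null(ranked, GeneSet("R", "", members),
                                   n_perm=100, seed=int(rng.integers(2**31)))
            rejections += res.p_perm <= 0.05
        assert 0.015 <= rejections / n_trials <= 0.105

    def test_too_few_permutations_rejected(self):
        ranked = RankedList(np.array(["a", "b", "c"], dtype=object),
                            np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValidationError):
            permutation_null(ranked, GeneSet("S", "", ("a",)), n_perm=10)


class TestFDRAndLeadingEdge:
    def test_decoy_only_collection_has_high_q(self):
        rng = np.random.default_rng(7)
        n = 400
        genes = np.array([f"g{i}" for i in range(n)], dtype=object)
        metrics = np.sort(rng.normal(size=n))[::-1]
        ranked = RankedList(genes, metrics)
        coll = GeneSetCollection([
            GeneSet(f"D{i}", "", tuple(rng.choice(genes, size=20, replace=False)))
            for i in range(12)
        ])
        results = analyze_collection(ranked, coll, n_perm=200, seed=1)
        qs = np.array([r.q_fdr for r in results])
        assert np.median(qs) > 0.3

    def test_bh_fallback_flag(self):
        rng = np.random.default_rng(8)
        ranked, members = _random_instance(rng, n_max=40)
        gs = GeneSet("S", "", tuple(members))
        scored = [permutation_null(ranked, gs, n_perm=100, seed=s) for s in (1, 2)]
        q = fdr_across_sets(scored, method="bh")
        assert len(q) == 2 and (q <= 1).all()

    def test_identical_leading_edges_intersect_to_themselves(self, gsea_results):
        from drivescan.gsea import EnrichmentResult
        r = gsea_results[0]
        a = EnrichmentResult("A", 0.5, 2.0, 0.001, 0.001, ["x", "y"], np.array([0, 1]), 2)
        b = EnrichmentResult("B", 0.5, 2.0, 0.001, 0.001, ["x", "y"], np.array([0, 1]), 2)
        assert intersect_leading_edges([a, b], q_threshold=0.01) == ["x", "y"]

    def test_disjoint_leading_edges_give_empty_core(self):
        from drivescan.gsea import EnrichmentResult
        a = EnrichmentResult("A", 0.5, 2.0, 0.001, 0.001, ["x"], np.array([0]), 1)
        b = EnrichmentResult("B", 0.5, 2.0, 0.001, 0.001, ["y"], np.array([1]), 1)
        assert intersect_leading_edges([a, b], q_threshold=0.01) == []

    def test_at_least_k_membership_rule(self):
        from drivescan.gsea import EnrichmentResult
        a = EnrichmentResult("A", 0.5, 2.0, 0.001, 0.001, ["x", "y"], np.array([0]), 2)
        b = EnrichmentResult("B", 0.5, 2.0, 0.001, 0.001, ["y", "z"], np.array([1]), 2)
        assert intersect_leading_edges([a, b], 0.01, membership_rule=1) == ["x", "y", "z"]

    def test_no_set_passes_threshold_fatal(self):
        from drivescan.gsea import EnrichmentResult
        a = EnrichmentResult("A", 0.5, 2.0, 0.5, 0.9, ["x"], np.array([0]), 1)
        with pytest.raises(ValidationError):
            intersect_leading_edges([a], q_threshold=0.01)

    def test_sets_without_members_are_skipped(self):
        ranked = RankedList(np.array(["a", "b", "c", "d"], dtype=object),
                            np.array([4.0, 3.0, 2.0, 1.0]))
        coll = GeneSetCollection([
            GeneSet("OK", "", ("a", "c")),
            GeneSet("MISSING", "", ("zz",)),
        ])
        results = analyze_collection(ranked, coll, n_perm=100, seed=0)
        assert [r.set_name for r in results] == ["OK"]
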