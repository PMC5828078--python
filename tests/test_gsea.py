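"""Ranked-list construction and the weighted-KS enrichment statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methyltrx.core import ValidationError
from methyltrx.gsea import (
    RankedList,
    build_methylation_gene_sets,
    build_ranked_list,
    gsea_enrichment_score,
    gsea_significance,
)

from conftest import brute_force_es


def ranked_from(scores: dict[str, float]) -> RankedList:
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedList([g for g, _ in items], np.array([s for _, s in items]))


FIVE = ranked_from({"g1": 3, "g2": 2, "g3": 1, "g4": -1, "g5": -2})


class TestBuildRankedList:
    def test_signed_log10_scores(self):
        diff = pd.DataFrame({
            "feature_id": ["up", "down", "null"],
            "mean_count": [10, 10, 10],
            "log2fc": [1.0, -1.0, 0.5],
            "pvalue": [0.001, 0.001, 1.0],
            "qvalue": [0.01, 0.01, 1.0],
        })
        ranked = build_ranked_list(diff)
        scores = dict(zip(ranked.genes, ranked.scores))
        assert scores["up"] == pytest.approx(3.0)
        assert scores["down"] == pytest.approx(-3.0)
        assert scores["null"] == 0.0

    def test_ordering_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        diff = pd.DataFrame({
            "feature_id": genes,
            "mean_count": 10.0,
            "log2fc": rng.normal(size=10),
            "pvalue": rng.uniform(0.001, 1.0, size=10),
            "qvalue": 0.5,
        })
        ranked = build_ranked_list(diff)
        score = np.sign(diff["log2fc"]) * -np.log10(diff["pvalue"])
        oracle = [g for g, _ in sorted(zip(genes, score), key=lambda t: (-t[1], t[0]))]
        assert ranked.genes == oracle
        assert np.all(np.diff(ranked.scores) <= 0)

    def test_missing_p_skipped(self):
        diff = pd.DataFrame({"feature_id": ["a", "b"], "mean_count": [9, 9],
                             "log2fc": [1.0, 1.0], "pvalue": [0.5, np.nan],
                             "qvalue": [0.5, np.nan]})
        assert build_ranked_list(diff).genes == ["a"]

    def test_integer_rank_option_preserves_order(self):
        diff = pd.DataFrame({"feature_id": ["a", "b", "c"], "mean_count": 9.0,
                             "log2fc": [2.0, 1.0, -1.0],
                             "pvalue": [0.001, 0.01, 0.005], "qvalue": 0.5})
        continuous = build_ranked_list(diff)
        integer = build_ranked_list(diff, integer_ranks=True)
        assert integer.genes == continuous.genes
        assert np.allclose(np.diff(integer.scores), -1.0)


class TestMethylationGeneSets:
    def _meth(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "mean_count",
                                           "log2fc", "pvalue", "qvalue"])

    def test_threshold_is_strict_per_kind(self):
        meth = self._meth([("gA|promoter", 9, 1, 0.001, 0.01),
                           ("gB|promoter", 9, 1, 0.01, 0.04),
                           ("gC|promoter", 9, 1, 0.1, 0.2)])
        sets = build_methylation_gene_sets(meth)
        assert sets["promoter"] == {"gA", "gB"}
        assert sets["exon"] == set()

    def test_gene_significant_in_two_kinds_joins_both_sets(self):
        meth = self._meth([("gA|promoter", 9, 1, 0.001, 0.01),
                           ("gA|exon", 9, 1, 0.001, 0.01)])
        sets = build_methylation_gene_sets(meth)
        assert "gA" in sets["promoter"] and "gA" in sets["exon"]

    def test_unparseable_region_id_rejected(self):
        meth = self._meth([("gA_promoter", 9, 1, 0.001, 0.01)])
        with pytest.raises(ValidationError):
            build_methylation_gene_sets(meth)


class TestEnrichmentScore:
    def test_all_hits_first_gives_unit_score(self):
        es, running, leading = gsea_enrichment_score(FIVE, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert leading == ["g1", "g2"]

    def test_hand_computed_running_sum(self):
        es, running, _ = gsea_enrichment_score(FIVE, {"g1", "g4"})
        assert np.allclose(running, [0.75, 0.75 - 1 / 3, 0.75 - 2 / 3, 1 / 3, 0.0],
                           atol=1e-9)
        assert es == pytest.approx(0.75)

    def test_universe_set_rejected(self):
        with pytest.raises(ValidationError):
            gsea_enrichment_score(FIVE, {"g1", "g2", "g3", "g4", "g5"})

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValidationError):
            gsea_enrichment_score(FIVE, {"absent"})

    def test_running_sum_ends_at_zero_and_es_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            scores = {f"g{i}": float(s) for i, s in
                      enumerate(np.sort(rng.normal(size=n))[::-1])}
            ranked = ranked_from(scores)
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(ranked.genes, size=size, replace=False))
            es, running, _ = gsea_enrichment_score(ranked, gene_set)
            assert abs(running[-1]) < 1e-9
            assert abs(es) <= 1.0 + 1e-12

    def test_negating_scores_and_reversing_negates_es(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            scores = {f"g{i}": float(s) for i, s in enumerate(rng.normal(size=12))}
            ranked = ranked_from(scores)
            flipped = ranked_from({g: -s for g, s in scores.items()})
            gene_set = set(rng.choice(list(scores), size=4, replace=False))
            es_fwd, _, _ = gsea_enrichment_score(ranked, gene_set)
            es_rev, _, _ = gsea_enrichment_score(flipped, gene_set)
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            ranked = ranked_from({f"g{i}": float(s)
                                  for i, s in enumerate(rng.normal(size=n))})
            size = int(rng.integers(1, n))
            gene_set = set(rng.choice(ranked.genes, size=size, replace=False))
            es, _, _ = gsea_enrichment_score(ranked, gene_set)
            oracle = brute_force_es(ranked.genes, ranked.scores, gene_set)
            assert es == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**32 - 1),
           st.floats(min_value=0.0, max_value=2.0))
    def test_weighted_variant_matches_oracle(self, seed, weight):
        rng = np.random.default_rng(seed)
        n = 12
        ranked = ranked_from({f"g{i}": float(s)
                              for i, s in enumerate(rng.normal(size=n))})
        gene_set = set(rng.choice(ranked.genes, size=4, replace=False))
        es, _, _ = gsea_enrichment_score(ranked, gene_set, weight=weight)
        oracle = brute_force_es(ranked.genes, ranked.scores, gene_set, weight=weight)
        assert es == pytest.approx(oracle, abs=1e-10)


class TestSignificance:
    def test_extremal_set_reaches_minimal_p(self):
        # 40-gene ranking: a random size-3 set essentially never attains
        # ES = 1, so the planted top-of-list set reaches the smallest
        # attainable smoothed p, 1 / (#same-sign nulls + 1).
        rng = np.random.default_rng(9)
        ranked = ranked_from({f"g{i:02d}": float(s) for i, s in
                              enumerate(np.sort(rng.normal(size=40))[::-1])})
        top3 = set(ranked.genes[:3])
        (res,) = gsea_significance(ranked, {"top": top3}, n_perm=999, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.pvalue < 0.01  # no null ties ES=1: p = 1/(#same-sign+1)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        ranked = FIVE
        gene_set = {"g1", "g4"}
        es_obs, _, _ = gsea_enrichment_score(ranked, gene_set)
        null = [brute_force_es(ranked.genes, ranked.scores, set(combo))
                for combo in itertools.combinations(ranked.genes, 2)]
        same = [e for e in null if (e >= 0) == (es_obs >= 0)]
        exhaustive = sum(abs(e) >= abs(es_obs) for e in same) / len(same)
        (res,) = gsea_significance(ranked, {"s": gene_set}, n_perm=10_000, seed=1)
        assert res.pvalue == pytest.approx(exhaustive, abs=0.02)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        n = 200
        ranked = ranked_from({f"g{i}": float(s)
                              for i, s in enumerate(rng.normal(size=n))})
        pvals = []
        for rep in range(100):
            gene_set = set(rng.choice(ranked.genes, size=15, replace=False))
            (res,) = gsea_significance(ranked, {"s": gene_set}, n_perm=200,
                                       seed=rep)
            pvals.append(res.pvalue)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValidationError):
            gsea_significance(FIVE, {"s": {"g1"}}, n_perm=10, seed=0)

    def test_qvalues_bh_across_sets(self):
        sets = {"a": {"g1", "g2"}, "b": {"g3", "g5"}, "c": {"g2", "g4"}}
        results = gsea_significance(FIVE, sets, n_perm=200, seed=3)
        from methyltrx.diffstats import bh_fdr
        expected = bh_fdr([r.pvalue for r in results])
        assert np.allclose([r.qvalue for r in results], expected)
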