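"""Permutation differential expression and hypergeometric enrichment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistromics.expression import (
    ExpressionMatrix,
    geneset_enrichment,
    geneset_enrichment_table,
    integrate_categories,
    lps_response_genes,
    sam_statistic,
    sam_test,
)
from cistromics.simulate import SyntheticConfig, generate_expression, simulate_two_group_matrix


class TestSamStatistic:
    def test_equal_means_give_zero_for_any_s0(self):
        for s0 in (0.0, 0.5, 3.0):
            assert sam_statistic([1, 2, 3], [3, 1, 2], s0=s0) == pytest.approx(0.0)

    def test_hand_computed_pooled_se_case(self):
        # group1={1,2}, group2={3,4}: pooled SE = sqrt(0.5), d = -2/0.7071
        d = sam_statistic([1, 2], [3, 4], s0=0.0)
        assert d == pytest.approx(-2.8284271247461903)

    def test_scale_homogeneity_at_zero_s0(self):
        g1, g2 = [1.0, 2.5, 2.0], [4.0, 3.0, 5.0]
        d = sam_statistic(g1, g2, s0=0.0)
        d_scaled = sam_statistic([3 * x for x in g1], [3 * x for x in g2], s0=0.0)
        assert d_scaled == pytest.approx(d)

    def test_matches_two_sample_t_at_zero_s0(self, rng):
        for _ in range(20):
            g1 = rng.normal(size=4)
            g2 = rng.normal(size=5)
            t, _ = stats.ttest_ind(g1, g2, equal_var=True)
            assert sam_statistic(g1, g2, s0=0.0) == pytest.approx(t)

    def test_zero_variance_zero_s0_is_error(self):
        with pytest.raises(ValueError):
            sam_statistic([1, 1], [2, 2], s0=0.0)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            sam_statistic([1], [2, 3])


class TestSamTest:
    def test_all_identical_matrix_gives_zero_calls(self):
        df = pd.DataFrame(
            np.ones((50, 6)), index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sam_test(df, df.columns[:3], df.columns[3:], n_permutations=100, seed=0)
        assert (res["call"] == "ns").all()

    def test_planted_effects_recovered_with_high_sensitivity(self):
        lfc = math.log2(2.5)
        sd = lfc / (4 * math.sqrt(2 / 4))  # per-gene t about 4
        df, g1, g2, planted = simulate_two_group_matrix(800, 80, lfc, sd, 4, seed=7)
        res = sam_test(df, g1, g2, n_permutations=200, seed=7, fdr_threshold=0.10)
        called = set(res.index[res["call"] != "ns"])
        assert len(called & planted) / len(planted) >= 0.8

    def test_q_values_monotone_in_abs_d(self):
        df, g1, g2, _ = simulate_two_group_matrix(300, 30, 1.5, 0.5, 3, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sam_test(df, g1, g2, n_permutations=100, seed=3)
        ordered = res.reindex(res["d_statistic"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["q_value"]) >= -1e-12).all()

    def test_deterministic_for_fixed_seed(self):
        df, g1, g2, _ = simulate_two_group_matrix(100, 10, 1.0, 0.4, 4, seed=1)
        r1 = sam_test(df, g1, g2, n_permutations=50, seed=5)
        r2 = sam_test(df, g1, g2, n_permutations=50, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_few_distinct_permutations_warns_and_uses_all(self):
        df, g1, g2, _ = simulate_two_group_matrix(50, 5, 1.0, 0.4, 2, seed=2)
        with pytest.warns(UserWarning, match="distinct permutations"):
            sam_test(df, g1, g2, n_permutations=1000, seed=0)

    def test_fold_filter_excludes_exactly_two_fold_gene(self):
        # a strict >2-fold filter must exclude a gene at exactly 2.0-fold
        # (noiseless signal rows; the fudge constant comes from the null rows)
        rng = np.random.default_rng(0)
        null = rng.normal(8.0, 0.3, size=(30, 8))
        exact2 = np.array([9.0] * 4 + [8.0] * 4)
        above2 = np.array([8.0 + 1.6] * 4 + [8.0] * 4)
        df = pd.DataFrame(
            np.vstack([exact2, above2, null]),
            index=["exact2", "above2"] + [f"null{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(8)],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sam_test(
                df, df.columns[:4], df.columns[4:], n_permutations=70, seed=0,
                fdr_threshold=0.5, fold_threshold=2.0,
            )
        assert res.loc["exact2", "q_value"] <= 0.5  # significant, yet filtered
        assert res.loc["exact2", "call"] == "ns"
        assert res.loc["above2", "call"] == "up"


class TestLpsResponseGenes:
    def _matrix(self, seed=0):
        cfg = SyntheticConfig(
            seed=seed, n_genes=0, planted_effect_genes=40,
            planted_log2_fc=2.0, noise_sd=0.3,
        )
        gene_ids = [f"g{i:04d}" for i in range(300)]
        expr, meta, truth = generate_expression(cfg, gene_ids)
        return ExpressionMatrix(expr, meta), truth

    def test_planted_induction_recovered(self):
        em, truth = self._matrix(seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            up, down = lps_response_genes(em, times=[4], seed=1)
        planted = set(truth.loc[truth["responsive"], "gene_id"])
        assert len(up & planted) / len(planted) >= 0.9
        assert len(down) <= 3

    def test_missing_baseline_is_error(self):
        em, _ = self._matrix()
        em_bad = ExpressionMatrix(
            em.values[[c for c in em.values.columns if "_t0_" not in c]],
            em.meta[~em.meta["sample_id"].str.contains("_t0_")],
        )
        with pytest.raises(ValueError, match="baseline"):
            lps_response_genes(em_bad, seed=0)


class TestIntegrateCategories:
    def _categories(self):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(12)],
             "category": [1] * 4 + [2] * 4 + [3] * 2 + [0] * 2}
        )

    def test_empty_de_gives_all_zero_counts(self):
        de = pd.DataFrame({"call": []}, index=pd.Index([], name="gene_id"))
        table, lists = integrate_categories({"KO_A": de}, self._categories())
        assert (table.to_numpy() == 0).all()

    def test_planted_category1_dependencies_counted_down(self):
        cats = self._categories()
        calls = {g: "down" if c == 1 else "ns" for g, c in zip(cats["gene_id"], cats["category"])}
        de = pd.DataFrame({"call": list(calls.values())}, index=pd.Index(calls.keys(), name="gene_id"))
        table, lists = integrate_categories({"KO_A": de, "KO_B": de}, cats)
        assert table.loc[1, ("KO_A", "down")] == 4
        assert table.loc[1, ("KO_B", "down")] == 4
        assert lists[(1, "KO_A", "down")] == ["g0", "g1", "g2", "g3"]

    def test_counts_partition_total_calls(self, rng):
        cats = self._categories()
        calls = rng.choice(["up", "down", "ns"], size=12)
        de = pd.DataFrame({"call": calls}, index=pd.Index(cats["gene_id"], name="gene_id"))
        table, _ = integrate_categories({"KO_A": de}, cats)
        assert table[("KO_A", "down")].sum() == (calls == "down").sum()
        assert table[("KO_A", "up")].sum() == (calls == "up").sum()


class TestGenesetEnrichment:
    def test_closed_form_case(self):
        # universe 10, geneset 5, selected 4, overlap 4: C(5,4)C(5,0)/C(10,4)
        universe = set("abcdefghij")
        p = geneset_enrichment(set("abcd"), set("abcde"), universe)
        assert p == pytest.approx(5 / 210)

    def test_degenerate_full_overlap_is_one(self):
        u = set("abc")
        assert geneset_enrichment(u, u, u) == pytest.approx(1.0)

    def test_disjoint_selection_is_in_upper_tail(self):
        universe = set(range(20))
        p = geneset_enrichment(set(range(5)), set(range(10, 18)), universe)
        assert p >= 0.5

    def test_subset_violations_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment({"x"}, {"a"}, {"a", "b"})
        with pytest.raises(ValueError):
            geneset_enrichment(set(), {"a"}, set())

    def test_matches_monte_carlo_within_three_se(self, rng):
        universe = list(range(30))
        geneset = set(range(8))
        selected = set(rng.choice(universe, size=10, replace=False).tolist())
        k = len(selected & geneset)
        p = geneset_enrichment(selected, geneset, set(universe))
        draws = 100_000
        sims = np.array([
            len(set(rng.choice(universe, size=10, replace=False).tolist()) & geneset) >= k
            for _ in range(2000)
        ])
        mc = sims.mean()
        se = math.sqrt(max(mc * (1 - mc), 1e-6) / len(sims))
        assert abs(p - mc) <= 3 * se + 1e-9

    def test_table_has_bh_q_values(self):
        universe = set(range(50))
        sets = {"s1": set(range(10)), "s2": set(range(20, 45))}
        df = geneset_enrichment_table(set(range(8)), sets, universe)
        assert {"p_value", "q_value"} <= set(df.columns)
        assert (df["q_value"] >= df["p_value"] - 1e-12).all()
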