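"""Gene-level statistics, weighted set statistics, permutation inference,
FDR, normalization and ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from goganpa.gsa import (
    ExpressionDataset,
    conserved_sets,
    count_significant,
    gene_statistics,
    normalized_scores,
    permutation_test,
    q_values,
    rank_by_z,
    read_cls,
    run_gsa,
    set_statistic,
    write_cls,
)
from goganpa.synthdata import (
    SimulationConfig,
    make_expression,
    make_gene_sets,
)
from goganpa.weighting import GeneSetCollection


def tiny_dataset(matrix, labels):
    genes = [f"g{i+1}" for i in range(len(matrix))]
    return ExpressionDataset(
        genes=genes, matrix=np.asarray(matrix, float), labels=labels
    )


class TestGeneStatistics:
    def test_equal_means_give_zero(self):
        data = tiny_dataset(
            [[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], [0, 0, 0, 1, 1, 1]
        )
        assert gene_statistics(data)["g1"] == pytest.approx(0.0)

    def test_hand_computed_pooled_t(self):
        # groups (1,2,3) vs (4,5,6): means 2 and 5, pooled var 1,
        # se = sqrt(2/3), t = -3 / sqrt(2/3)
        data = tiny_dataset([[1, 2, 3, 4, 5, 6]], [0, 0, 0, 1, 1, 1])
        assert gene_statistics(data)["g1"] == pytest.approx(
            -3 / math.sqrt(2 / 3)
        )

    def test_constant_gene_gets_zero(self):
        data = tiny_dataset(
            [[5.0] * 6, [1, 2, 3, 4, 5, 6]], [0, 0, 0, 1, 1, 1]
        )
        assert gene_statistics(data)["g1"] == 0.0

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            tiny_dataset([[1, 2, 3]], [0, 0, 1])

    def test_welch_differs_under_unequal_variance(self):
        # unequal group sizes, unequal variances: pooled and Welch differ
        data = tiny_dataset(
            [[0.0, 0.1, -0.1, 10, -10, 5, -5, 8]], [0] * 3 + [1] * 5
        )
        pooled = gene_statistics(data)["g1"]
        welch = gene_statistics(data, welch=True)["g1"]
        assert pooled != pytest.approx(welch)


class TestSetStatistic:
    def test_unweighted_mean_absolute(self):
        d = {"a": 1.0, "b": -2.0, "c": 3.0}
        assert set_statistic(d, None, ["a", "b", "c"]) == pytest.approx(2.0)

    def test_weighted_arithmetic(self):
        d = {"a": 1.0, "b": -2.0, "c": 3.0}
        w = {"a": 2.0, "b": 1.0, "c": 1.0}
        assert set_statistic(d, w, ["a", "b", "c"]) == pytest.approx(7 / 4)

    def test_singleton_weight_cancels(self):
        d = {"a": -1.7}
        assert set_statistic(d, {"a": 42.0}, ["a"]) == pytest.approx(1.7)

    def test_unmeasured_genes_dropped(self):
        d = {"a": 2.0}
        assert set_statistic(d, None, ["a", "missing"]) == pytest.approx(2.0)

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            set_statistic({"a": 1.0}, None, ["x", "y"])


class TestPermutationTest:
    def _setup(self, seed=0, n_genes=12, n=4):
        cfg = SimulationConfig(
            n_genes=n_genes, n_sets=3, set_size=(4, 4), n_samples=n, seed=seed
        )
        sets = make_gene_sets(cfg)
        data = make_expression(cfg, gene_sets=sets)
        return data, sets

    def test_constant_matrix_gives_p_one(self):
        data = tiny_dataset(
            np.ones((4, 8)), [0] * 4 + [1] * 4
        )
        coll = GeneSetCollection(
            sets={"S": frozenset(data.genes)}, min_size=1, max_size=10
        )
        _, _, p = permutation_test(data, coll, None, B=50, seed=1)
        assert p["S"] == 1.0

    def test_dominant_effect_gives_exact_zero_p(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 20)) * 0.01
        X[:, 10:] += 100.0  # overwhelming group difference
        data = tiny_dataset(X, [0] * 10 + [1] * 10)
        coll = GeneSetCollection(
            sets={"S": frozenset(data.genes)}, min_size=1, max_size=10
        )
        _, _, p = permutation_test(data, coll, None, B=200, seed=3)
        assert p["S"] == 0.0

    def test_sampled_p_converges_to_exhaustive_enumeration(self):
        """3-vs-2 toy: the sampled p matches the exact 10-arrangement
        enumeration within 3 standard errors."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 5))
        labels = np.array([0, 0, 0, 1, 1])
        data = tiny_dataset(X, labels)
        coll = GeneSetCollection(
            sets={"S": frozenset(data.genes[:3])}, min_size=1, max_size=10
        )
        T_obs, _, p_hat = permutation_test(data, coll, None, B=4000, seed=5)

        def stat(lbl):
            d = gene_statistics(
                ExpressionDataset(genes=data.genes, matrix=X, labels=lbl)
            )
            return set_statistic(d, None, data.genes[:3])

        exact_hits = 0
        arrangements = list(itertools.combinations(range(5), 2))
        for ones in arrangements:
            lbl = np.array([1 if i in ones else 0 for i in range(5)])
            if stat(lbl) >= T_obs["S"] - 1e-12:
                exact_hits += 1
        p_exact = exact_hits / len(arrangements)
        se = math.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(p_hat["S"] - p_exact) <= 3 * se + 1e-9

    def test_seed_reproducibility(self):
        data, sets = self._setup(seed=6)
        r1 = permutation_test(data, sets, None, B=100, seed=7)
        r2 = permutation_test(data, sets, None, B=100, seed=7)
        pd.testing.assert_series_equal(r1[2], r2[2])
        np.testing.assert_array_equal(r1[1].stats, r2[1].stats)

    def test_smoothing_flag(self):
        data, sets = self._setup(seed=8)
        _, _, p_plain = permutation_test(data, sets, None, B=100, seed=9)
        _, _, p_smooth = permutation_test(
            data, sets, None, B=100, seed=9, smoothing=True
        )
        np.testing.assert_allclose(
            p_smooth.to_numpy(), (p_plain.to_numpy() * 100 + 1) / 101
        )

    def test_weights_change_the_statistic(self, star_fixture):
        _, coll, table = star_fixture
        cfg = SimulationConfig(
            n_genes=50, n_sets=1, set_size=(10, 10), effect_size=2.0,
            de_mode="hub_only", seed=10,
        )
        data = make_expression(cfg, weight_table=table)
        T_w, _, _ = permutation_test(data, coll, table, B=10, seed=11)
        T_u, _, _ = permutation_test(data, coll, None, B=10, seed=11)
        assert T_w["STAR"] > T_u["STAR"]


def brute_force_bh(p):
    """Literal step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestQValues:
    def test_single_p(self):
        assert q_values(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_fixpoint(self):
        q = q_values(np.array([0.2] * 5))
        np.testing.assert_allclose(q, 0.2)

    def test_textbook_example(self):
        q = q_values(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_step_up(self, seed):
        p = np.random.default_rng(seed).uniform(size=37)
        np.testing.assert_allclose(q_values(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = np.random.default_rng(11).uniform(size=60)
        _, q_ref, _, _ = sm.multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q_values(p), q_ref)

    def test_storey_rescales_by_pi0(self):
        p = np.random.default_rng(12).uniform(size=200)
        q_bh = q_values(p)
        q_st = q_values(p, method="storey")
        pi0 = min(1.0, (p > 0.5).mean() / 0.5)
        np.testing.assert_allclose(q_st, np.minimum(q_bh * pi0, 1.0))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_q_bounds_and_order_consistency(self, ps):
        p = np.array(ps)
        q = q_values(p)
        assert ((q >= 0) & (q <= 1)).all()
        # same p implies same q
        for a in range(len(p)):
            for b in range(len(p)):
                if p[a] == p[b]:
                    assert q[a] == q[b]


class TestNormalizedScores:
    def _ens(self, stats, names=None):
        from goganpa.gsa import PermutationEnsemble

        stats = np.asarray(stats, float)
        names = names or [f"s{i}" for i in range(stats.shape[1])]
        return PermutationEnsemble(
            B=stats.shape[0], stats=stats, seed=0, set_names=names
        )

    def test_observed_at_median_gives_zero(self):
        ens = self._ens(np.array([[1.0], [2.0], [3.0]]))
        z = normalized_scores(pd.Series({"s0": 2.0}), ens)
        assert z["s0"] == pytest.approx(0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        base = rng.standard_normal((200, 1))
        obs = pd.Series({"s0": 1.3})
        z1 = normalized_scores(obs, self._ens(base))
        z2 = normalized_scores(
            obs * 2.5 + 7, self._ens(base * 2.5 + 7)
        )
        assert z1["s0"] == pytest.approx(z2["s0"])

    def test_median_sd_oracle(self):
        rng = np.random.default_rng(14)
        stats = rng.standard_normal((500, 4))
        obs = pd.Series(rng.standard_normal(4), index=[f"s{i}" for i in range(4)])
        z = normalized_scores(obs, self._ens(stats))
        for i in range(4):
            ref = (obs.iloc[i] - np.median(stats[:, i])) / stats[:, i].std(
                ddof=1
            )
            assert z.iloc[i] == pytest.approx(ref)

    def test_zero_spread_reported_missing(self):
        ens = self._ens(np.ones((10, 1)))
        z = normalized_scores(pd.Series({"s0": 1.0}), ens)
        assert np.isnan(z["s0"])

    def test_pooled_scope(self):
        rng = np.random.default_rng(15)
        stats = rng.standard_normal((300, 3)) + [0, 5, 10]
        obs = pd.Series([0.0, 5.0, 10.0], index=["s0", "s1", "s2"])
        z = normalized_scores(obs, self._ens(stats), scope="pooled")
        med, sd = np.median(stats), stats.std(ddof=1)
        np.testing.assert_allclose(
            z.to_numpy(), (obs.to_numpy() - med) / sd
        )


class TestRankingAndCounting:
    def test_strictly_decreasing_ranks_in_order(self):
        z = pd.Series([5.0, 4.0, 3.0], index=list("abc"))
        assert rank_by_z(z).tolist() == [1, 2, 3]

    def test_competition_ranking_with_ties(self):
        z = pd.Series([3.0, 3.0, 1.0], index=list("abc"))
        assert rank_by_z(z).tolist() == [1, 1, 3]

    def test_sort_position_oracle(self):
        rng = np.random.default_rng(16)
        vals = rng.integers(0, 10, size=50).astype(float)
        z = pd.Series(vals, index=[f"s{i}" for i in range(50)])
        ranks = rank_by_z(z)
        srt = sorted(vals, reverse=True)
        for name, v in z.items():
            assert ranks[name] == srt.index(v) + 1

    def test_conserved_sets_inclusive_boundary(self):
        tables = [
            pd.Series({"a": 37, "b": 90}),
            pd.Series({"a": 80, "b": 10}),
            pd.Series({"a": 1, "b": 5}),
        ]
        assert conserved_sets(tables, 80) == ["a"]

    def test_conserved_requires_presence_everywhere(self):
        tables = [pd.Series({"a": 1, "b": 2}), pd.Series({"a": 3})]
        assert conserved_sets(tables, 80) == ["a"]

    def test_conserved_empty_and_zero_threshold(self):
        tables = [pd.Series(dtype=float), pd.Series(dtype=float)]
        assert conserved_sets(tables, 80) == []
        tables = [pd.Series({"a": 1}), pd.Series({"a": 1})]
        assert conserved_sets(tables, 0) == []

    def test_count_significant(self):
        q = np.array([0.01, 0.15, 0.151, 0.9])
        assert count_significant(q, 0.15) == 2
        assert count_significant(np.array([]), 0.15) == 0
        assert count_significant(q, 1.0) == 4


class TestRunGsa:
    def _inputs(self, seed=17):
        cfg = SimulationConfig(
            n_genes=20, n_sets=5, set_size=(4, 4),
            effect_size=1.5, de_mode="uniform", seed=seed,
        )
        sets = make_gene_sets(cfg)
        data = make_expression(cfg, gene_sets=sets)
        return data, sets

    def test_unit_weights_reduce_to_unweighted(self):
        data, sets = self._inputs()
        unit = {g: 1.0 for g in data.genes}
        a = run_gsa(data, sets, unit, B=100, seed=18)
        b = run_gsa(data, sets, None, B=100, seed=18)
        pd.testing.assert_frame_equal(a, b)

    def test_bit_identical_under_same_seed(self):
        data, sets = self._inputs()
        a = run_gsa(data, sets, None, B=100, seed=19)
        b = run_gsa(data, sets, None, B=100, seed=19)
        pd.testing.assert_frame_equal(a, b)

    def test_output_columns_and_bounds(self):
        data, sets = self._inputs()
        res = run_gsa(data, sets, None, B=50, seed=20)
        assert list(res.columns) == [
            "size_used", "T", "p", "q", "Z", "rank", "significant",
        ]
        assert res["p"].between(0, 1).all()
        assert res["q"].between(0, 1).all()
        assert sorted(res["rank"].dropna()) == list(range(1, len(res) + 1))


class TestClsIO:
    def test_roundtrip(self, tmp_path):
        labels = np.array([0, 0, 0, 1, 1, 0, 1])
        path = tmp_path / "pheno.cls"
        write_cls(labels, path, names=("WT", "MUT"))
        np.testing.assert_array_equal(read_cls(path), labels)

    def test_three_class_rejected(self, tmp_path):
        path = tmp_path / "bad.cls"
        path.write_text("6 3 1\n# a b c\na a b b c c\n")
        with pytest.raises(ValueError):
            read_cls(path)
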