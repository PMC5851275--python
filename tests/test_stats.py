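import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_stepup, exhaustive_zscore, hypergeometric_zscore, \
    pearson_chi2
from sgenes.families import Thresholds
from sgenes.stats import (
    bh_adjust,
    chi_square_enrichment,
    chi_square_test,
    degree_summary,
    resampling_zscore,
)


class TestChiSquare:
    def test_uniform_table_has_zero_statistic(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computable_table(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert res.p_value == pytest.approx(0.00982, rel=1e-2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_closed_form_pearson(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 5)), int(rng.integers(2, 6)))
        table = rng.integers(1, 60, size=shape)
        res = chi_square_test(table)
        assert res.chi2 == pytest.approx(pearson_chi2(table), abs=1e-9)
        assert res.dof == (shape[0] - 1) * (shape[1] - 1)

    def test_zero_margin_names_the_degenerate_column(self):
        with pytest.raises(ValueError, match="column 1"):
            chi_square_test([[5, 0], [7, 0]])

    def test_family_of_tests_gets_bh_adjustment(self):
        tables = {"t1": [[40, 10], [10, 40]], "t2": [[20, 10], [10, 20]],
                  "t3": [[15, 15], [15, 16]]}
        results = chi_square_enrichment(tables, adjust=True)
        adj = bh_stepup([r.p_value for r in results])
        for r, expected in zip(results, adj):
            assert r.adjusted_p == pytest.approx(expected, abs=1e-12)
            assert r.adjusted_p >= r.p_value


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_manual_step_up_and_is_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(bh_stepup(pvals), abs=1e-12)
        assert all(a >= p for a, p in zip(adj, pvals))
        # sorting the inputs sorts the outputs the same way
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        ranked = [adj[i] for i in order]
        assert ranked == sorted(ranked)


class TestResamplingZ:
    def test_exhaustive_matches_subset_enumeration(self):
        pool = [True, True, False, False]
        res = resampling_zscore(2, pool, 2, exhaustive=True)
        assert res.mean == pytest.approx(1.0)
        assert res.sd == pytest.approx(0.5774, abs=1e-4)
        assert res.z_score == pytest.approx(1.732, abs=1e-3)
        assert res.z_score == pytest.approx(exhaustive_zscore(2, pool, 2))

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_matches_oracles_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pool = [bool(rng.random() < 0.5) for _ in range(n)]
        if not 0 < sum(pool) < n:
            pool[0] = not pool[0]
        k = int(rng.integers(1, n))
        obs = int(rng.integers(0, k + 1))
        res = resampling_zscore(obs, pool, k, exhaustive=True)
        assert res.z_score == pytest.approx(exhaustive_zscore(obs, pool, k))
        assert res.z_score == pytest.approx(
            hypergeometric_zscore(obs, pool, k))

    def test_observed_at_mean_gives_zero_z(self):
        pool = [True, True, False, False]
        res = resampling_zscore(1, pool, 2, exhaustive=True)
        assert res.z_score == 0.0

    def test_same_seed_is_deterministic(self):
        pool = [True] * 30 + [False] * 70
        a = resampling_zscore(10, pool, 20, seed=9)
        b = resampling_zscore(10, pool, 20, seed=9)
        assert a == b

    def test_degenerate_pool_is_error(self):
        with pytest.raises(ValueError):
            resampling_zscore(1, [True, True, True], 3)

    def test_null_z_is_rarely_extreme(self):
        # observed drawn from the pool itself: |Z| < 3 in >= 99% of runs
        rng = np.random.default_rng(123)
        pool = [bool(rng.random() < 0.3) for _ in range(200)]
        flags = np.array(pool)
        t = Thresholds()
        extreme = 0
        n_runs = 1000
        for i in range(n_runs):
            idx = rng.choice(200, size=60, replace=False)
            obs = int(flags[idx].sum())
            res = resampling_zscore(obs, pool, 60, t, seed=10_000 + i)
            if abs(res.z_score) >= 3:
                extreme += 1
        assert extreme / n_runs <= 0.01


class TestDegreeSummary:
    def test_median_and_quartiles(self):
        degrees = {"a": 10, "b": 36, "c": 60}
        out = degree_summary(degrees, {g: "S" for g in degrees})
        assert out.loc["S", "median"] == 36

    def test_single_gene_collapses_quartiles(self):
        out = degree_summary({"a": 7}, {"a": "S"})
        row = out.loc["S"]
        assert row["median"] == row["q1"] == row["q3"] == 7

    def test_identical_multisets_give_identical_summaries(self):
        degrees = {"a": 1, "b": 5, "c": 9, "x": 1, "y": 5, "z": 9}
        groups = {"a": "G1", "b": "G1", "c": "G1",
                  "x": "G2", "y": "G2", "z": "G2"}
        out = degree_summary(degrees, groups,
                             essential={"a": True, "x": True})
        assert out.loc["G1"].tolist() == out.loc["G2"].tolist()
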