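"""Rank statistics, clustering, and attribution pipeline."""

import numpy as np
import pandas as pd
import pytest

from lumenflow.analysis import (
    attribute_factors,
    cluster_cases,
    dunn_test,
    multifactor_compare,
)
from lumenflow.oracles import kmeans_1d_optimal, synthetic_sweep


class TestMultifactorCompare:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "cs": [1, 2, 3, 4, 5] * 2})
        out = multifactor_compare(df, "g", "cs")
        assert out["test"] == "mann-whitney"
        assert out["p_value"] > 0.9

    def test_exact_rank_sum_minimum_for_n3(self):
        # fully separated groups of three: the exact two-sided p is 0.1
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3, "cs": [1, 2, 3, 101, 102, 103]})
        out = multifactor_compare(df, "g", "cs")
        assert out["p_value"] == pytest.approx(0.1)

    def test_kruskal_rejects_large_shift(self, rng):
        base = rng.normal(0, 1, 12)
        df = pd.DataFrame(
            {
                "g": ["a"] * 12 + ["b"] * 12 + ["c"] * 12,
                "cs": np.concatenate([base, base, base + 25.0]),
            }
        )
        out = multifactor_compare(df, "g", "cs")
        assert out["test"] == "kruskal-wallis"
        assert out["p_value"] < 0.05
        dunn = out["dunn"]
        sep = dunn[(dunn.group_a == "a") & (dunn.group_b == "c")]
        assert float(sep.p_adj.iloc[0]) < 0.05
        same = dunn[(dunn.group_a == "a") & (dunn.group_b == "b")]
        assert float(same.p_adj.iloc[0]) > 0.5

    def test_group_summaries_report_quartiles(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "cs": [1, 2, 3, 4, 10, 20, 30, 40]})
        out = multifactor_compare(df, "g", "cs")
        assert out["summary"].loc["b", "median"] == 25.0

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "cs": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than two"):
            multifactor_compare(df, "g", "cs")

    def test_holm_adjustment_is_monotone(self, rng):
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")}
        out = dunn_test(groups)
        assert (out.p_adj >= out.p_raw - 1e-15).all()
        assert (out.p_adj <= 1.0).all()


class TestClustering:
    def test_two_obvious_clusters(self):
        df = pd.DataFrame({"cs": [0.1, 0.1, 0.9, 0.9]})
        out = cluster_cases(df, k=2, seed=0)
        means = out.attrs["cluster_means"]
        assert means[0] == pytest.approx(0.1)
        assert means[1] == pytest.approx(0.9)
        assert list(out.cluster) == [0, 0, 1, 1]

    def test_k_equals_n_isolates_every_case(self):
        df = pd.DataFrame({"cs": [0.1, 0.3, 0.55, 0.8]})
        out = cluster_cases(df, k=4, seed=0)
        assert sorted(out.cluster) == [0, 1, 2, 3]

    def test_matches_dynamic_programming_optimum(self, rng):
        cs = np.sort(rng.random(18))
        df = pd.DataFrame({"cs": cs})
        out = cluster_cases(df, k=3, seed=1)
        labels_dp, sse_dp = kmeans_1d_optimal(cs, 3)
        sse_km = sum(
            ((cs[out.cluster == i] - cs[out.cluster == i].mean()) ** 2).sum()
            for i in range(3)
        )
        assert sse_km == pytest.approx(sse_dp, rel=1e-9)

    def test_k_exceeding_distinct_values_rejected(self):
        df = pd.DataFrame({"cs": [0.2, 0.2, 0.2, 0.8]})
        with pytest.raises(ValueError, match="distinct"):
            cluster_cases(df, k=3, seed=0)

    def test_deterministic_under_seed(self, rng):
        df = pd.DataFrame({"cs": rng.random(30)})
        a = cluster_cases(df, k=4, seed=7)
        b = cluster_cases(df, k=4, seed=7)
        assert (a.cluster == b.cluster).all()


class TestAttribution:
    def test_dominant_factor_ranks_first(self):
        df = synthetic_sweep(11, dominant="pocket_volume")
        res = attribute_factors(df, seed=11)
        assert res.ranking.index[0] == "pocket_volume"

    def test_scaled_features_within_unit_interval(self):
        df = synthetic_sweep(3)
        res = attribute_factors(df, seed=3)
        X = res.feature_frame
        assert float(X.min().min()) >= 0.0
        assert float(X.max().max()) <= 1.0

    def test_shap_additivity_to_machine_precision(self):
        df = synthetic_sweep(5)
        res = attribute_factors(df, seed=5)
        assert res.additivity_error() < 1e-6

    def test_constant_response_rejected(self):
        df = synthetic_sweep(1)
        df["cs"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            attribute_factors(df, seed=1)

    def test_small_table_warns(self):
        df = synthetic_sweep(2).head(12)
        with pytest.warns(UserWarning, match="cases"):
            attribute_factors(df, seed=2)

    def test_grid_search_path_returns_params_from_grid(self):
        df = synthetic_sweep(4)
        tiny = {"n_estimators": [50], "learning_rate": [0.05, 0.2], "max_depth": [3]}
        res = attribute_factors(df, seed=4, grid_search=True, param_grid=tiny)
        assert res.best_params["learning_rate"] in (0.05, 0.2)
        assert np.isfinite(res.rmse)
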