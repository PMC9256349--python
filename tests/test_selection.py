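import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dbpkit as dk
from dbpkit.errors import ConfigError
from dbpkit.features import FeatureTable

from _oracles import brute_force_mic


def table_from_columns(columns: dict[str, list], labels) -> FeatureTable:
    names = list(columns)
    values = np.column_stack([np.asarray(columns[n], float) for n in names])
    ids = [f"s{i}" for i in range(values.shape[0])]
    return FeatureTable(ids=ids, names=names, values=values, labels=labels)


class TestVarianceRanking:
    def test_orders_by_spread_with_stable_ties(self):
        table = table_from_columns({
            "const": [0.5] * 4,
            "wide": [0.0, 1.0, 0.0, 1.0],
            "narrow": [0.4, 0.6, 0.4, 0.6],
            "wide_dup": [1.0, 0.0, 1.0, 0.0],
        }, labels=[0, 0, 1, 1])
        ranking = dk.score_variance(table)
        assert ranking.ordered_names == ["wide", "wide_dup", "narrow", "const"]
        assert ranking.scores["wide"] == pytest.approx(0.25)
        assert ranking.scores["const"] == 0.0

    def test_single_row_rejected(self):
        table = table_from_columns({"f": [1.0]}, labels=[1])
        with pytest.raises(ConfigError):
            dk.score_variance(table)


class TestChi2Ranking:
    def test_hand_computed_statistic(self):
        # label-identical feature, balanced n=4: O=(0,2), E=(1,1) -> 2.0
        table = table_from_columns({
            "matchlabel": [0.0, 0.0, 1.0, 1.0],
            "flat": [1.0, 1.0, 1.0, 1.0],
        }, labels=[0, 0, 1, 1])
        ranking = dk.score_chi2(table)
        assert ranking.scores["matchlabel"] == pytest.approx(2.0)
        assert ranking.scores["flat"] == pytest.approx(0.0)
        assert ranking.ordered_names[0] == "matchlabel"

    def test_statistic_scales_linearly_with_feature(self):
        base = [0.1, 0.4, 0.9, 0.2, 0.8, 0.7]
        labels = [0, 0, 0, 1, 1, 1]
        t1 = table_from_columns({"f": base}, labels)
        t3 = table_from_columns({"f": [3 * v for v in base]}, labels)
        s1 = dk.score_chi2(t1).scores["f"]
        s3 = dk.score_chi2(t3).scores["f"]
        assert s3 == pytest.approx(3 * s1)

    def test_negative_values_rejected(self):
        table = table_from_columns({"f": [-0.1, 0.2]}, labels=[0, 1])
        with pytest.raises(ConfigError):
            dk.score_chi2(table)

    def test_row_permutation_invariance(self, null_table):
        from dbpkit.evaluation import minmax_normalize

        norm = minmax_normalize(null_table)
        perm = np.random.default_rng(1).permutation(norm.n_samples)
        shuffled = FeatureTable(
            ids=[norm.ids[i] for i in perm], names=list(norm.names),
            values=norm.values[perm], labels=norm.labels[perm])
        for scorer in (dk.score_chi2, dk.score_variance):
            a, b = scorer(norm), scorer(shuffled)
            assert a.ordered_names == b.ordered_names
            for name in norm.names:
                assert a.scores[name] == pytest.approx(b.scores[name])


class TestMicStatistic:
    def test_perfect_functional_relationship(self):
        x = np.arange(16.0)
        assert dk.mic_statistic(x, x) == pytest.approx(1.0)

    def test_constant_input_scores_zero(self):
        x = np.arange(16.0)
        assert dk.mic_statistic(x, np.zeros(16)) == 0.0

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            a, b = dk.mic_statistic(x, y), dk.mic_statistic(y, x)
            assert a == pytest.approx(b, abs=1e-12)
            assert 0.0 <= a <= 1.0

    def test_invariant_to_strictly_monotone_transform(self, rng):
        x = rng.normal(size=40)
        y = rng.integers(0, 2, size=40).astype(float)
        assert dk.mic_statistic(x, y) == pytest.approx(
            dk.mic_statistic(np.exp(x), y), abs=1e-12)

    def test_dp_matches_exhaustive_enumeration_small_n(self, rng):
        """The DP grid search must agree with explicit enumeration of all
        admissible grids for every small input."""
        for case in range(60):
            n = int(rng.integers(4, 11))
            if case % 2:
                x = rng.integers(0, 4, size=n).astype(float)
                y = rng.integers(0, 3, size=n).astype(float)
            else:
                x = rng.normal(size=n)
                y = x + rng.normal(scale=0.5, size=n)
            assert dk.mic_statistic(x, y) == pytest.approx(
                brute_force_mic(x, y), abs=1e-10)


class TestMicRanking:
    def test_label_feature_ranked_first_noise_low(self, rng):
        n = 200
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        table = table_from_columns({
            "label_copy": labels.astype(float),
            "noise1": rng.random(n),
            "noise2": rng.random(n),
        }, labels)
        ranking = dk.score_mic(table)
        assert ranking.ordered_names[0] == "label_copy"
        assert ranking.scores["label_copy"] == pytest.approx(1.0)
        assert ranking.scores["noise1"] < 0.3
        assert ranking.scores["noise2"] < 0.3


class TestEmbeddedRanking:
    def test_constant_feature_ranked_last_and_rf_importance_normalized(
            self, small_table):
        from dbpkit.evaluation import minmax_normalize

        norm = minmax_normalize(small_table)
        values = np.column_stack([norm.values, np.zeros(norm.n_samples)])
        table = FeatureTable(ids=list(norm.ids),
                             names=list(norm.names) + ["const"],
                             values=values, labels=norm.labels)
        for est in ("lr", "linsvm", "rf"):
            ranking = dk.score_embedded(table, est, seed=0)
            assert ranking.ordered_names[-1] == "const"
            assert ranking.scores["const"] == 0.0
        rf = dk.score_embedded(table, "rf", seed=0)
        assert sum(rf.scores.values()) == pytest.approx(1.0)

    def test_planted_dimension_ranked_first(self, rng):
        # one 3-sigma dimension among 49 noise dims, avg features
        from conftest import make_feature_table
        from dbpkit.evaluation import minmax_normalize

        table = minmax_normalize(make_feature_table(
            seed=21, n_per_class=100, d=50, effect=3.0, informative=1,
            categories=("avg",)))
        for est in ("lr", "linsvm", "rf"):
            ranking = dk.score_embedded(table, est, seed=0)
            assert ranking.ordered_names[0] == "avg_0"

    def test_single_class_rejected(self):
        table = table_from_columns({"f": [0.1, 0.2, 0.3]}, labels=[1, 1, 1])
        with pytest.raises(ConfigError):
            dk.score_embedded(table, "lr")

    def test_deterministic_under_seed(self, small_table):
        a = dk.score_embedded(small_table, "rf", seed=5)
        b = dk.score_embedded(small_table, "rf", seed=5)
        assert a.ordered_names == b.ordered_names
        assert a.scores == b.scores


class TestTopPercent:
    @pytest.mark.parametrize("n,p,expected", [
        (580, 20, 116), (580, 30, 174), (1280, 20, 256),
        (37120, 5, 1856), (37120, 4, 1485), (10, 1, 1),
    ])
    def test_ceil_rule(self, n, p, expected):
        assert dk.top_percent_count(n, p) == expected

    def test_out_of_range_percent(self):
        with pytest.raises(ConfigError):
            dk.top_percent_count(100, 0)
        with pytest.raises(ConfigError):
            dk.top_percent_count(100, 101)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(1, 100), st.integers(1, 100), st.integers(5, 60))
    def test_nesting_property(self, p1, p2, n_features):
        names = [f"f{i}" for i in range(n_features)]
        ranking = dk.FeatureRanking(
            method="variance", ordered_names=names,
            scores={n: 0.0 for n in names})
        lo, hi = sorted((p1, p2))
        small = dk.select_top_percent(ranking, lo).selected_names
        big = dk.select_top_percent(ranking, hi).selected_names
        assert set(small) <= set(big)

    def test_origin_string(self, small_table):
        ranking = dk.score_variance(small_table)
        assert dk.select_top_percent(ranking, 20).origin == "Variance20"


class TestRegularizers:
    def test_constant_features_never_selected(self, null_table):
        from dbpkit.evaluation import minmax_normalize

        norm = minmax_normalize(null_table)
        values = np.column_stack([norm.values, np.zeros(norm.n_samples)])
        table = FeatureTable(ids=list(norm.ids),
                             names=list(norm.names) + ["const"],
                             values=values, labels=norm.labels)
        for method in ("lasso", "lassolars", "elasticnet"):
            sel = dk.select_by_regularizer(
                table, method, params={"alpha": 0.002}, seed=0)
            assert "const" not in sel.selected_names
            assert len(sel.selected_names) <= table.n_features

    def test_provenance_records_parameters(self, small_table):
        from dbpkit.evaluation import minmax_normalize

        sel = dk.select_by_regularizer(
            minmax_normalize(small_table), "lasso",
            params={"alpha": 0.002, "max_iter": 50000}, seed=0)
        assert sel.origin == "Lasso"
        assert sel.provenance["params"]["alpha"] == 0.002
        assert sel.provenance["count"] == len(sel.selected_names)


class TestRfeCv:
    def test_output_is_subset_of_start(self, small_table):
        ranking = dk.score_variance(small_table)
        start = dk.select_top_percent(ranking, 5)
        refined = dk.rfe_cv(small_table, start, "lr", folds=4, step=2, seed=0)
        assert set(refined.selected_names) <= set(start.selected_names)
        assert len(refined.selected_names) >= 1
        assert refined.origin == "Variance5_RFE"

    def test_singleton_start_returned_unchanged(self, small_table):
        start = dk.SelectionResult(origin="One",
                                   selected_names=[small_table.names[0]])
        refined = dk.rfe_cv(small_table, start, "lr", folds=4, seed=0)
        assert refined.selected_names == start.selected_names

    def test_separating_feature_survives_elimination(self, rng):
        n = 40
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        columns = {"signal": labels + rng.normal(scale=0.05, size=n)}
        for j in range(20):
            columns[f"noise{j}"] = rng.random(n)
        table = table_from_columns(columns, labels)
        start = dk.SelectionResult(origin="All",
                                   selected_names=list(table.names))
        refined = dk.rfe_cv(table, start, "linsvm", folds=4, step=4, seed=0)
        assert "signal" in refined.selected_names

    def test_empty_start_rejected(self, small_table):
        start = dk.SelectionResult(origin="Empty", selected_names=[])
        with pytest.raises(ConfigError):
            dk.rfe_cv(small_table, start, "lr")
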