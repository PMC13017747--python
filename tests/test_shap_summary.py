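"""Attribution correctness (local accuracy, dummy, symmetry, tree oracle)
and the mean-|SHAP| summary layer."""

import numpy as np
import pandas as pd
import pytest
import lightgbm as lgb

from riskdomains import (
    CohortSpec,
    CohortTable,
    ModelSpec,
    ShapMatrix,
    SplitSpec,
    age_stratified_shap,
    calibrate_ranking,
    compute_shap,
    fit_model,
    generate_cohort,
    mean_abs_shap,
    predict_proba,
    split_cohort,
    top_factors,
)
from riskdomains.model_zoo import FittedModel

from conftest import make_table


def _cohort_from_arrays(X, y, columns):
    n = len(y)
    rng = np.random.default_rng(0)
    feats = pd.DataFrame(X, columns=columns)
    feats["age"] = rng.uniform(50, 100, n)
    feats["gender"] = rng.binomial(1, 0.5, n).astype(float)
    return CohortTable(
        ids=pd.Index(range(n)), features=feats, outcome=pd.Series(y), age_col="age", gender_col="gender"
    )


# ---------------------------------------------------------------------------
# Brute-force path-dependent oracle on the dumped tree structure


def _tree_expectation(node, x, known):
    """E[f(x) | x_known] under path-dependent conditioning: unknown splits
    are weighted by their training counts."""
    if "leaf_value" in node:
        return node["leaf_value"]
    j = node["split_feature"]
    left, right = node["left_child"], node["right_child"]
    if j in known:
        child = left if x[j] <= node["threshold"] else right
        return _tree_expectation(child, x, known)
    cl = left.get("internal_count", left.get("leaf_count"))
    cr = right.get("internal_count", right.get("leaf_count"))
    el = _tree_expectation(left, x, known)
    er = _tree_expectation(right, x, known)
    return (cl * el + cr * er) / (cl + cr)


def _brute_force_tree_shap(booster, x):
    """Exact Shapley values over feature subsets with the path-dependent
    conditional expectation, summed over trees (2 features only)."""
    from itertools import combinations
    from math import factorial

    dump = booster.dump_model()
    p = 2

    def v(S):
        return sum(
            _tree_expectation(t["tree_structure"], x, set(S)) for t in dump["tree_info"]
        )

    phi = np.zeros(p)
    for j in range(p):
        rest = [k for k in range(p) if k != j]
        for size in range(p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for S in combinations(rest, size):
                phi[j] += w * (v(tuple(sorted(S + (j,)))) - v(S))
    return phi, v(())


class TestTreeAttribution:
    def test_stump_attributes_only_split_feature(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(size=400)
        X = np.column_stack([x0, rng.normal(size=400)])
        y = (x0 > 0).astype(int)
        t = _cohort_from_arrays(X, y, ["x0", "x1"])
        m = fit_model(
            ModelSpec(name="lightgbm", hyperparams={"n_estimators": 1, "num_leaves": 2}),
            t,
            feature_subset=["x0", "x1"],
        )
        mat = compute_shap(m, t)
        raw = m.handle.booster_.predict(t.features[["x0", "x1"]].to_numpy(), raw_score=True)
        np.testing.assert_allclose(mat.values[:, 0], raw - mat.base_value, atol=1e-10)
        np.testing.assert_array_equal(mat.values[:, 1], 0.0)

    def test_matches_brute_force_path_dependent_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 2))
        logit = 1.5 * X[:, 0] - 1.0 * X[:, 1] + 0.8 * X[:, 0] * X[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-logit)))
        t = _cohort_from_arrays(X, y, ["f0", "f1"])
        m = fit_model(
            ModelSpec(name="lightgbm", hyperparams={"n_estimators": 10, "num_leaves": 4}),
            t,
            feature_subset=["f0", "f1"],
        )
        mat = compute_shap(m, t)
        for i in (0, 7, 123, 499):
            phi, base = _brute_force_tree_shap(m.handle.booster_, X[i])
            np.testing.assert_allclose(mat.values[i], phi, atol=1e-9)
            assert mat.base_value == pytest.approx(base, abs=1e-9)

    def test_local_accuracy_and_dummy_on_synthetic_cohort(self):
        spec = CohortSpec(
            n=1000,
            domain_sizes={"demography": 2, "socioeconomic": 9, "psychology": 9},
            target_prevalence=0.3,
            missing_rate=0.05,
            seed=3,
        )
        table, _ = generate_cohort(spec)
        # add a constant column: the booster can never split on it
        feats = table.features.copy()
        feats["dummy"] = 1.0
        table2 = CohortTable(
            ids=table.ids, features=feats, outcome=table.outcome,
            age_col=table.age_col, gender_col=table.gender_col,
        )
        train, _ = split_cohort(table2, SplitSpec(seed=0))
        m = fit_model(ModelSpec(name="lightgbm"), train)
        mat = compute_shap(m, table2)
        raw = m.handle.booster_.predict(
            table2.features[m.feature_names].to_numpy(dtype=float), raw_score=True
        )
        assert np.abs(mat.row_sums() - raw).max() < 1e-6
        dummy_col = m.feature_names.index("dummy")
        np.testing.assert_array_equal(mat.values[:, dummy_col], 0.0)


class TestPermutationAttribution:
    def _logistic_model(self, X, y, columns):
        t = _cohort_from_arrays(X, y, columns)
        return t, fit_model(ModelSpec(name="logistic"), t, feature_subset=columns)

    def test_exact_route_local_accuracy_and_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        X = np.column_stack([x, x, rng.normal(size=200)])  # duplicated feature
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        t, m = self._logistic_model(X, y, ["a", "a_dup", "b"])
        mat = compute_shap(m, t, method="permutation", seed=0)
        # local accuracy: attributions + base reproduce each row's margin
        p = predict_proba(m, t)
        margin = np.log(p / (1 - p))
        assert np.abs(mat.row_sums() - margin).max() < 1e-6
        # symmetry: exactly duplicated columns share their attribution
        s = mean_abs_shap(mat)
        assert s.value("a") == pytest.approx(s.value("a_dup"), abs=1e-6)

    def test_sampling_route_locally_accurate_and_seeded(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 14))
        y = rng.binomial(1, 0.5, 12)
        while y.min() == y.max():
            y = rng.binomial(1, 0.5, 12)
        cols = [f"c{i}" for i in range(14)]
        t, m = self._logistic_model(X, y, cols)
        mat1 = compute_shap(m, t, method="permutation", seed=5, background_size=16)
        mat2 = compute_shap(m, t, method="permutation", seed=5, background_size=16)
        np.testing.assert_array_equal(mat1.values, mat2.values)
        p = predict_proba(m, t)
        margin = np.log(p / (1 - p))
        assert np.abs(mat1.row_sums() - margin).max() < 1e-6

    def test_too_many_features_for_sampling_errors(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 101))
        y = rng.binomial(1, 0.5, 30)
        cols = [f"c{i}" for i in range(101)]
        t, m = self._logistic_model(X, y, cols)
        with pytest.raises(ValueError, match="subsample"):
            compute_shap(m, t, method="permutation")


class TestSummaries:
    def _toy_matrix(self):
        values = np.array(
            [
                [0.0, -1.0, 0.3],
                [0.0, 1.0, -0.1],
            ]
        )
        return ShapMatrix(values=values, base_value=0.5, feature_names=["zero", "big", "small"])

    def test_mean_abs_and_ranking(self):
        s = mean_abs_shap(self._toy_matrix())
        assert s.value("zero") == 0.0
        assert s.value("big") == 1.0
        assert s.value("small") == pytest.approx(0.2)
        assert s.ranking() == ["big", "small", "zero"]
        assert s.table.loc[s.table["feature"] == "zero", "rank"].iloc[0] == 3

    def test_top_factors_threshold(self):
        s = mean_abs_shap(self._toy_matrix())
        assert top_factors(s, threshold=0.1) == ["big", "small"]
        assert top_factors(s, threshold=5.0) == []
        assert top_factors(s, threshold=0.0) == ["big", "small"]

    def test_threshold_refused_on_probability_scale(self):
        mat = self._toy_matrix()
        mat.scale = "probability"
        s = mean_abs_shap(mat)
        with pytest.raises(ValueError, match="log-odds"):
            top_factors(s, threshold=0.1)

    def test_tie_break_by_name(self):
        values = np.array([[0.5, 0.5]])
        s = mean_abs_shap(ShapMatrix(values=values, base_value=0.0, feature_names=["b", "a"]))
        assert s.ranking() == ["a", "b"]


class TestAgeStratified:
    def test_single_bin_equals_overall(self, plain_table):
        rng = np.random.default_rng(0)
        mat = ShapMatrix(
            values=rng.normal(size=(plain_table.n, 2)),
            base_value=0.0,
            feature_names=["age", "x0"],
        )
        strat = age_stratified_shap(mat, plain_table, bins=[(50.0, 110.0)])
        overall = mean_abs_shap(mat)
        for f in ("age", "x0"):
            assert strat.table.loc[f].iloc[0] == pytest.approx(overall.value(f))

    def test_overlapping_bins_error(self, plain_table):
        mat = ShapMatrix(
            values=np.zeros((plain_table.n, 1)), base_value=0.0, feature_names=["age"]
        )
        with pytest.raises(ValueError, match="overlap"):
            age_stratified_shap(mat, plain_table, bins=[(50, 70), (65, 110)])

    def test_empty_and_small_bins_flagged(self):
        t = make_table(n=50, seed=1)
        ages = np.linspace(50, 69.5, 50)
        feats = t.features.copy()
        feats["age"] = ages
        t2 = CohortTable(ids=t.ids, features=feats, outcome=t.outcome, age_col="age", gender_col="gender")
        mat = ShapMatrix(values=np.ones((50, 1)), base_value=0.0, feature_names=["age"])
        strat = age_stratified_shap(mat, t2, bins=[(50, 60), (60, 70), (70, 110)])
        assert strat.counts["70+"] == 0
        assert "70+" in strat.unstable_bins
        assert np.isnan(strat.table["70+"]).all()
        # 25-person bins are below the stability floor of 30
        assert "50-60" in strat.unstable_bins

    def test_age_gap_uncovered_errors(self):
        t = make_table(n=30, seed=2)
        mat = ShapMatrix(values=np.zeros((30, 1)), base_value=0.0, feature_names=["age"])
        with pytest.raises(ValueError, match="not covered"):
            age_stratified_shap(mat, t, bins=[(50, 60)])


class TestCalibrateRanking:
    def _summary(self, features, means):
        values = np.abs(np.array(means))[None, :]
        return mean_abs_shap(ShapMatrix(values=values, base_value=0.0, feature_names=features))

    def test_identical_summaries_align_identically(self):
        a = self._summary(["age", "income", "smoke"], [2.0, 1.0, 0.5])
        out = calibrate_ranking([a, a], labels=["x", "y"])
        assert list(out.index) == ["age", "income", "smoke"]
        assert not out.isna().any().any()

    def test_reference_only_feature_shows_missing_cell(self):
        a = self._summary(["age", "income"], [2.0, 1.0])
        b = self._summary(["age"], [1.5])
        out = calibrate_ranking([a, b], labels=["ref", "other"])
        assert np.isnan(out.loc["income", "other"])
        assert out.loc["income", "ref"] == 1.0

    def test_order_follows_reference_not_others(self):
        ref = self._summary(["a", "b", "c"], [3.0, 2.0, 1.0])
        other = self._summary(["c", "b", "a"], [9.0, 5.0, 1.0])
        out = calibrate_ranking([ref, other], labels=["ref", "other"])
        assert list(out.index) == ["a", "b", "c"]

    def test_disjoint_features_error(self):
        a = self._summary(["x"], [1.0])
        b = self._summary(["y"], [1.0])
        with pytest.raises(ValueError, match="shared"):
            calibrate_ranking([a, b])


def test_age_dominates_ranking_in_planted_cohort():
    """The planted process gives age the largest effect; the fitted model's
    attribution ranking must recover it at the top."""
    table, _ = generate_cohort(CohortSpec(n=3000, seed=9))
    train, _ = split_cohort(table, SplitSpec(seed=0))
    m = fit_model(ModelSpec(name="lightgbm"), train)
    s = mean_abs_shap(compute_shap(m, table))
    assert s.ranking()[0] == "age"
    assert s.value("age") > 0.1
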