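"""Shapley attributions: exhaustive oracles, local accuracy, ranking."""

from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from ppgbp.estimation import LinearDeltaBP, fit_rf
from ppgbp.importance import (RankingReport, kernel_shap, rank_agreement,
                              ranking_coefficient, shap_linear, shap_tree)


def _exact_shap(predict, background, x):
    """Exhaustive Shapley enumeration with interventional expectations."""
    background = np.atleast_2d(background)
    M = len(x)

    def v(subset):
        hybrid = background.copy()
        for j in subset:
            hybrid[:, j] = x[j]
        return float(np.mean(predict(hybrid)))

    phi = np.zeros(M)
    features = list(range(M))
    for j in features:
        rest = [f for f in features if f != j]
        for size in range(M):
            for subset in combinations(rest, size):
                w = (factorial(len(subset)) * factorial(M - len(subset) - 1)
                     / factorial(M))
                phi[j] += w * (v(subset + (j,)) - v(subset))
    return phi


class TestKernelShap:
    def test_linear_identity_independent_features(self):
        rng = np.random.default_rng(0)
        coef = np.array([2.0, -1.5, 0.7])
        model = LinearDeltaBP(coef=coef, intercept=1.0,
                              support=np.ones(3, bool),
                              feature_names=list("abc"))
        bg = rng.normal(size=(200, 3))
        X = rng.normal(size=(5, 3))
        attr = shap_linear(model, bg, X)
        expected = coef * (X - bg.mean(axis=0))
        assert np.allclose(attr.phi, expected, atol=1e-6)

    def test_background_mean_gets_zero_attribution(self):
        model = LinearDeltaBP(coef=np.array([1.0, 2.0]), intercept=0.0,
                              support=np.ones(2, bool),
                              feature_names=["a", "b"])
        bg = np.array([[0.0, 1.0], [2.0, 3.0]])
        attr = shap_linear(model, bg, bg.mean(axis=0)[None, :])
        assert np.allclose(attr.phi, 0.0, atol=1e-9)

    def test_matches_exhaustive_enumeration_m3(self):
        rng = np.random.default_rng(1)

        def predict(X):
            X = np.atleast_2d(X)
            return X[:, 0] ** 2 + 2 * X[:, 1] * X[:, 2] - X[:, 2]

        bg = rng.normal(size=(30, 3))
        x = rng.normal(size=3)
        attr = kernel_shap(predict, bg, x[None, :])
        oracle = _exact_shap(predict, bg, x)
        assert np.allclose(attr.phi[0], oracle, atol=1e-6)

    def test_local_accuracy(self):
        rng = np.random.default_rng(2)

        def predict(X):
            X = np.atleast_2d(X)
            return np.sin(X[:, 0]) + X[:, 1] ** 2

        bg = rng.normal(size=(40, 2))
        X = rng.normal(size=(6, 2))
        attr = kernel_shap(predict, bg, X)
        assert np.max(attr.local_accuracy_error(predict(X))) < 1e-6

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            kernel_shap(lambda X: X[:, 0], np.empty((0, 2)), np.zeros((1, 2)))


class TestTreeShap:
    def test_stump_attributes_single_feature(self):
        X = np.array([[0.0, 5.0], [1.0, -5.0], [2.0, 5.0], [3.0, -5.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        tree = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        attr = shap_tree(tree, X, X)
        assert np.allclose(attr.phi[:, 1], 0.0, atol=1e-12)
        assert np.max(attr.local_accuracy_error(tree.predict(X))) < 1e-9

    def test_depth2_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0) * 2.0 + (X[:, 1] > 0.5) * 1.0
        tree = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X, y)
        bg = X[:10]
        for x in X[:5]:
            attr = shap_tree(tree, bg, x[None, :])
            oracle = _exact_shap(tree.predict, bg, x)
            assert np.allclose(attr.phi[0], oracle, atol=1e-9)

    def test_forest_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 3))
        y = X[:, 0] * X[:, 1] + X[:, 2]
        model = fit_rf(X, y, mtry=2, n_trees=10, seed=0)
        bg = X[:8]
        x = X[11]
        attr = shap_tree(model, bg, x[None, :])
        oracle = _exact_shap(model.predict, bg, x)
        assert np.allclose(attr.phi[0], oracle, atol=1e-8)

    def test_phi0_is_mean_background_prediction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        model = fit_rf(X, y, mtry=1, n_trees=5, seed=1)
        attr = shap_tree(model, X[:20], X[:3])
        assert attr.phi0 == pytest.approx(model.predict(X[:20]).mean(),
                                          abs=1e-9)

    def test_local_accuracy_forest(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 3))
        y = np.where(X[:, 0] > 0, X[:, 1], -X[:, 2])
        model = fit_rf(X, y, mtry=2, n_trees=15, seed=2)
        bg, Xe = X[:15], X[20:30]
        attr = shap_tree(model, bg, Xe)
        assert np.max(attr.local_accuracy_error(model.predict(Xe))) < 1e-6

    def test_unused_feature_zero_phi(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 3))
        y = 3.0 * X[:, 0]                 # features 1, 2 never used
        tree = DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y)
        attr = shap_tree(tree, X[:10], X[:10])
        assert np.allclose(attr.phi[:, 1:], 0.0, atol=1e-12)

    def test_feature_mismatch_rejected(self):
        X = np.zeros((10, 3))
        tree = DecisionTreeRegressor().fit(X, np.zeros(10))
        with pytest.raises(ValueError):
            shap_tree(tree, X, np.zeros((1, 5)))

    def test_consistency_two_feature_toy(self):
        """Strengthening a feature's contribution never lowers its |phi|."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        phis = []
        for gain in (1.0, 3.0):
            y = gain * X[:, 0] + X[:, 1]
            tree = DecisionTreeRegressor(max_depth=2, random_state=0).fit(
                X, y)
            attr = shap_tree(tree, X, X)
            phis.append(np.mean(np.abs(attr.phi[:, 0])))
        assert phis[1] >= phis[0]


class TestRanking:
    def test_dominant_feature_scores_one(self):
        folds = [{"A": 5.0, "B": 1.0}, {"A": 7.0, "B": 2.0}]
        report = ranking_coefficient(folds)
        med = report.median_coefficients()
        assert med["A"] == 1.0 and med["B"] == 0.0

    def test_ranks_match_sort_oracle(self):
        imp = {"a": 0.3, "b": 0.9, "c": 0.1, "d": 0.5}
        report = ranking_coefficient([imp])
        pf = report.per_fold.set_index("feature")
        order = sorted(imp, key=imp.get, reverse=True)
        for rank, feat in enumerate(order, start=1):
            assert pf.loc[feat, "rank"] == rank
        # strictly decreasing coefficient in rank
        coeffs = pf.loc[order, "coefficient"].to_numpy()
        assert np.all(np.diff(coeffs) < 0)
        assert coeffs[0] == 1.0 and coeffs[-1] == 0.0

    def test_all_ties_give_half(self):
        report = ranking_coefficient([{"a": 1.0, "b": 1.0, "c": 1.0}])
        assert np.allclose(report.summary["median"], 0.5)

    def test_empty_folds_rejected(self):
        with pytest.raises(ValueError):
            ranking_coefficient([])


class TestResultsIntegration:
    def test_both_model_families_rank_true_driver_first(self):
        from ppgbp.estimation import DeltaBPModel
        from tests_helpers import toy_dataset

        reports = {}
        for kind, grid, trees in (("lasso_ols", [0.0], 10),
                                  ("rf", [2], 10)):
            ds = toy_dataset(n_participants=4, rows_per=25)
            model = DeltaBPModel(ds, model_kind=kind, feature_set="all",
                                 hyper_grid=grid, n_trees=trees)
            res = model.fit(seed=0)
            reports[kind] = res.feature_importance(background_size=15,
                                                   max_rows=20)
        for kind, report in reports.items():
            med = report.median_coefficients()
            assert med.idxmax() == "f0", kind
            assert med["f0"] == 1.0
        # the two families agree on the overall ordering direction
        assert rank_agreement(reports["lasso_ols"], reports["rf"]) > 0


class TestRankAgreement:
    def _report(self, med):
        summary = pd.DataFrame({"feature": list(med),
                                "median": list(med.values()),
                                "min": 0.0, "max": 1.0})
        return RankingReport(per_fold=pd.DataFrame(), summary=summary)

    def test_identical_rankings_tau_one(self):
        r = self._report({"a": 1.0, "b": 0.6, "c": 0.2})
        assert rank_agreement(r, r) == pytest.approx(1.0)

    def test_reversed_rankings_tau_minus_one(self):
        a = self._report({"a": 1.0, "b": 0.6, "c": 0.2})
        b = self._report({"a": 0.2, "b": 0.6, "c": 1.0})
        assert rank_agreement(a, b) == pytest.approx(-1.0)

    def test_matches_pair_counting_oracle(self):
        a_med = {"a": 0.9, "b": 0.5, "c": 0.7, "d": 0.1}
        b_med = {"a": 0.8, "b": 0.9, "c": 0.3, "d": 0.2}
        a, b = self._report(a_med), self._report(b_med)
        feats = list(a_med)
        conc = disc = 0
        for i in range(len(feats)):
            for j in range(i + 1, len(feats)):
                s = ((a_med[feats[i]] - a_med[feats[j]])
                     * (b_med[feats[i]] - b_med[feats[j]]))
                conc += s > 0
                disc += s < 0
        oracle = (conc - disc) / (len(feats) * (len(feats) - 1) / 2)
        assert rank_agreement(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_disjoint_features_rejected(self):
        a = self._report({"a": 1.0, "b": 0.5})
        b = self._report({"x": 1.0, "y": 0.5})
        with pytest.raises(ValueError):
            rank_agreement(a, b)
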