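"""Estimators, nested LOSOCV, baseline reference, model comparison."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppgbp.dataset import CalibratedDataset
from ppgbp.estimation import (DeltaBPModel, baseline_reference,
                              compare_models, fit_lasso_ols, fit_rf,
                              nested_losocv)


def _toy_dataset(n_participants=5, rows_per=30, n_features=4, noise=0.5,
                 seed=0, nonlinear=False):
    """Cohort dataset with a known feature -> dBP link."""
    rng = np.random.default_rng(seed)
    frames = []
    for p in range(n_participants):
        X = rng.normal(size=(rows_per, n_features))
        if nonlinear:
            y = 8.0 * (X[:, 0] > 0) + noise * rng.normal(size=rows_per)
        else:
            y = 3.0 * X[:, 0] + noise * rng.normal(size=rows_per)
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_features)])
        df["dsbp"] = y
        df["participant_id"] = f"P{p}"
        df["t"] = np.arange(rows_per, dtype=float)
        # mark a third of the rows as augmentation-only
        df["augmented"] = (np.arange(rows_per) % 3) == 1
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    feature_cols = [f"f{j}" for j in range(n_features)]
    return CalibratedDataset(
        X=table[["t"] + feature_cols], y=table[["dsbp"]],
        participant_ids=table["participant_id"].to_numpy(),
        augmented_mask=table["augmented"].to_numpy(),
        dynamic_features=feature_cols, demographic_features=[])


class TestLassoOls:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=80)
        model = fit_lasso_ols(X, y, lam=0.0)
        design = np.column_stack([np.ones(80), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(model.coef, beta[1:], atol=1e-6)
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_huge_lambda_empty_support(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 4))
        y = X[:, 0] + rng.normal(size=60)
        model = fit_lasso_ols(X, y, lam=1e9)
        assert not model.support.any()
        assert np.allclose(model.predict(X), y.mean())

    def test_support_recovery_two_features(self):
        rng = np.random.default_rng(2)
        n = 500
        X = rng.normal(size=(n, 2))
        y = 3.0 * X[:, 0] + 0.3 * rng.normal(size=n)
        # moderate shrinkage keeps the true signal, kills the noise column
        model = fit_lasso_ols(X, y, lam=2.0 * n * 0.05)
        assert model.support[0] and not model.support[1]
        assert 2.5 <= model.coef[0] <= 3.5

    def test_support_recovery_power_over_replicates(self):
        """LASSO+OLS finds the true support in >= 90% of seeded replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            X = rng.normal(size=(n, 6))
            y = 3.0 * X[:, 0] - 2.0 * X[:, 1] + 0.5 * rng.normal(size=n)
            model = fit_lasso_ols(X, y, lam=2.0 * n * 0.2)
            if (model.support[0] and model.support[1]
                    and not model.support[2:].any()):
                hits += 1
        assert hits >= 18

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_ols(np.zeros((10, 2)), np.zeros(10), lam=-1.0)


class TestForest:
    def test_constant_target(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        model = fit_rf(X, np.full(50, 4.2), mtry=2, n_trees=20, seed=0)
        assert np.allclose(model.predict(X), 4.2)

    def test_predictions_bounded_by_training_range(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        y = rng.normal(size=200)
        model = fit_rf(X, y, mtry=3, n_trees=30, seed=1)
        pred = model.predict(rng.normal(size=(100, 3)) * 5)
        assert pred.min() >= y.min() - 1e-12
        assert pred.max() <= y.max() + 1e-12

    def test_learns_step_function(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(1000, 2))
        y = (X[:, 0] > 0).astype(float)
        model = fit_rf(X[:800], y[:800], mtry=2, n_trees=100, seed=2)
        rmse = np.sqrt(np.mean((model.predict(X[800:]) - y[800:]) ** 2))
        assert rmse < 0.2

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        a = fit_rf(X, y, mtry=2, n_trees=20, seed=7).predict(X)
        b = fit_rf(X, y, mtry=2, n_trees=20, seed=7).predict(X)
        assert np.array_equal(a, b)

    def test_invalid_mtry(self):
        with pytest.raises(ValueError):
            fit_rf(np.zeros((10, 3)), np.zeros(10), mtry=5)


class TestNestedLosocv:
    def test_fold_count_equals_participants(self):
        ds = _toy_dataset(n_participants=5)
        folds = nested_losocv(ds, "lasso_ols", feature_set="all",
                              hyper_grid=[0.0])
        assert len(folds) == 5

    def test_single_element_grid_used_everywhere(self):
        ds = _toy_dataset(n_participants=4)
        folds = nested_losocv(ds, "rf", feature_set="all", hyper_grid=[2],
                              n_trees=10)
        assert all(f.hyperparameter == 2 for f in folds)

    def test_no_leakage_structurally(self):
        ds = _toy_dataset(n_participants=4)
        folds = nested_losocv(ds, "lasso_ols", feature_set="all",
                              hyper_grid=[0.0])
        pids = set(ds.participant_ids)
        for f in folds:
            assert f.test_participant in pids
            # evaluation rows are exactly the participant's unaugmented rows
            mask = (ds.participant_ids == f.test_participant) \
                & ~ds.augmented_mask
            assert len(f.y_true) == mask.sum()

    def test_linear_link_recovery_high_correlation(self):
        ds = _toy_dataset(n_participants=6, rows_per=40, noise=0.3, seed=8)
        folds = nested_losocv(ds, "lasso_ols", feature_set="all", seed=3)
        rhos = [f.rho_p for f in folds]
        assert np.median(rhos) >= 0.9

    def test_rf_beats_linear_on_nonlinear_link(self):
        ds = _toy_dataset(n_participants=6, rows_per=50, noise=0.3,
                          seed=9, nonlinear=True)
        lin = nested_losocv(ds, "lasso_ols", feature_set="all",
                            hyper_grid=[0.0], seed=0)
        rf = nested_losocv(ds, "rf", feature_set="all", hyper_grid=[2],
                           n_trees=60, seed=0)
        assert (np.median([f.rmse for f in rf])
                <= np.median([f.rmse for f in lin]))

    def test_metric_consistency_recomputation(self):
        ds = _toy_dataset(n_participants=4)
        folds = nested_losocv(ds, "lasso_ols", feature_set="all",
                              hyper_grid=[0.0])
        for f in folds:
            assert f.rmse == pytest.approx(
                np.sqrt(np.mean((f.y_true - f.y_pred) ** 2)), abs=1e-12)
            assert f.mae == pytest.approx(
                np.mean(np.abs(f.y_true - f.y_pred)), abs=1e-12)
            if len(f.y_true) >= 3:
                assert f.rho_p == pytest.approx(
                    stats.pearsonr(f.y_true, f.y_pred)[0], abs=1e-12)
            assert f.rmse >= f.mae >= 0

    def test_too_few_participants_rejected(self):
        ds = _toy_dataset(n_participants=2)
        with pytest.raises(ValueError):
            nested_losocv(ds, "lasso_ols", feature_set="all",
                              hyper_grid=[0.0])


class TestBaseline:
    def test_zero_targets_zero_errors(self):
        ds = _toy_dataset(n_participants=3)
        ds.y["dsbp"] = 0.0
        base = baseline_reference(ds)
        assert np.allclose(base["rmse"], 0.0)
        assert np.allclose(base["mae"], 0.0)

    def test_arithmetic_oracle(self):
        ds = _toy_dataset(n_participants=1, rows_per=3)
        # unaugmented rows are positions 0 and 2
        ds.y.loc[[0, 2], "dsbp"] = [3.0, -4.0]
        base = baseline_reference(ds)
        assert base.loc[0, "rmse"] == pytest.approx(np.sqrt(12.5))
        assert base.loc[0, "mae"] == pytest.approx(3.5)

    def test_rho_reported_missing(self):
        base = baseline_reference(_toy_dataset(n_participants=3))
        assert base["rho_p"].isna().all()


def _brute_wilcoxon_p(d):
    """Exact two-sided signed-rank p by enumeration of all sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [np.array(signs) @ ranks
             for signs in product([0, 1], repeat=n)]
    w_all = np.array(w_all)
    mean_w = n * (n + 1) / 4
    extreme = np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12
    return extreme.mean()


class TestComparison:
    def _metrics(self, values):
        return pd.DataFrame({"participant": range(len(values)),
                             "rho_p": values, "rmse": values,
                             "mae": values})

    def test_identical_vectors_p_one(self):
        m = self._metrics(np.linspace(0, 1, 8))
        table = compare_models({"A": m, "B": m.copy()})
        assert np.allclose(table.frame["p"], 1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=6)
        b = a + rng.normal(0.5, 1.0, size=6)
        table = compare_models({"A": self._metrics(a),
                                "B": self._metrics(b)},
                               metric_names=("rmse",))
        expected = _brute_wilcoxon_p(a - b)
        assert table.frame["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bh_adjustment_step_up_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(11)
        frames = {k: self._metrics(rng.normal(size=7)) for k in "ABC"}
        table = compare_models(frames)
        assert np.all(table.frame["p_adjusted"] >= table.frame["p"] - 1e-12)


class TestModelResultsApi:
    def test_fit_returns_results_with_summary(self):
        ds = _toy_dataset(n_participants=4)
        model = DeltaBPModel(ds, model_kind="lasso_ols", feature_set="all",
                             hyper_grid=[0.0])
        res = model.fit(seed=0)
        text = res.summary()
        assert "rho_p" in text and "rmse" in text
        mf = res.metrics_frame()
        assert len(mf) == 4

    def test_from_dataframe_roundtrip(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "f0": rng.normal(size=60), "f1": rng.normal(size=60),
            "dsbp": rng.normal(size=60),
            "participant_id": np.repeat(list("abc"), 20),
            "augmented": False, "t": np.tile(np.arange(20.0), 3)})
        model = DeltaBPModel.from_dataframe(
            df, ["f0", "f1"], model_kind="lasso_ols", feature_set="all",
            hyper_grid=[0.0])
        res = model.fit()
        assert len(res.folds) == 3
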