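"""ΔBP estimation models and nested leave-one-subject-out evaluation.

Two model families estimate the change in blood pressure from calibrated
waveform features plus demographics:

* LASSO + OLS — an L1-penalised selection pass (shrinkage parameter
  lambda) followed by an ordinary-least-squares refit on the surviving
  support;
* random forest — 300 squared-error trees with the per-node feature
  subsample size (mtry) as the tuned hyperparameter.

`DeltaBPModel` wraps a :class:`~ppgbp.dataset.CalibratedDataset`; its
``fit`` runs nested leave-one-subject-out cross-validation (the outer loop
holds out one participant for testing, the inner loop tunes the
hyperparameter by RMSE on the remaining participants) and returns a
`DeltaBPResults` carrying the per-fold predictions, metrics, summary table,
plotting and SHAP-based feature importance.  Training and validation use
the augmented rows; evaluation always uses the original (unaugmented) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso
from statsmodels.stats.multitest import multipletests

from .dataset import DEMOGRAPHIC_FEATURES, CalibratedDataset
from .ecg_features import ECG_FEATURES
from .ppg_features import ALL_PPG_FEATURES

__all__ = [
    "FoldResult", "ComparisonTable", "LinearDeltaBP", "ForestDeltaBP",
    "fit_lasso_ols", "fit_rf", "DeltaBPModel", "DeltaBPResults",
    "nested_losocv", "baseline_reference", "compare_models",
    "select_feature_columns",
]


# ---------------------------------------------------------------------------
# feature-set selection


def select_feature_columns(columns: list, feature_set: str) -> list:
    """Restrict a column list to one of the ppg / ecg / ppg+ecg / pat sets.

    Demographics (including the BP calibration value) are part of every
    set; the hybrid-calibration scheme depends on them.
    """
    cols = set(columns)
    demo = [c for c in DEMOGRAPHIC_FEATURES if c in cols]
    ppg = [c for c in ALL_PPG_FEATURES if c in cols]
    ecg = [c for c in ECG_FEATURES if c in cols]
    pat = [c for c in ("PAT",) if c in cols]
    everything = [c for c in columns if c not in demo and c != "t"]
    picks = {"ppg": ppg, "ecg": ecg, "ppg+ecg": ppg + ecg, "pat": pat,
             "all": everything}
    if feature_set not in picks:
        raise ValueError(f"unknown feature set '{feature_set}'")
    return picks[feature_set] + demo


# ---------------------------------------------------------------------------
# model families


@dataclass
class LinearDeltaBP:
    """LASSO-selected, OLS-refitted linear model on standardised features."""

    coef: np.ndarray            # on the original feature scale
    intercept: float
    support: np.ndarray         # boolean mask of selected features
    feature_names: list

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def fit_lasso_ols(X: np.ndarray, y: np.ndarray, lam: float,
                  feature_names: list | None = None) -> LinearDeltaBP:
    """L1 selection at shrinkage ``lam`` then OLS refit on the support.

    ``lam`` parameterises the penalty as lam * sum |beta| added to the raw
    residual sum of squares computed on standardised features; lam = 0 is
    plain OLS, and an empty support degrades to an intercept-only model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    names = feature_names or [f"x{j}" for j in range(m)]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        support = np.ones(m, dtype=bool)
    else:
        # sklearn's objective is (1/2n)||y - Zb||^2 + alpha ||b||_1
        model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True,
                      max_iter=20000)
        model.fit(Z, y)
        support = model.coef_ != 0
    if not support.any():
        return LinearDeltaBP(coef=np.zeros(m), intercept=float(y.mean()),
                             support=support, feature_names=names)
    design = np.column_stack([np.ones(n), Z[:, support]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = np.zeros(m)
    coef[support] = beta[1:] / sd[support]
    intercept = float(beta[0] - (mu[support] * coef[support]).sum())
    return LinearDeltaBP(coef=coef, intercept=intercept, support=support,
                         feature_names=names)


def lambda_grid(X: np.ndarray, y: np.ndarray, size: int = 30,
                min_ratio: float = 1e-4) -> np.ndarray:
    """Data-driven log-spaced shrinkage grid [lam_max * min_ratio, lam_max]."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    lam_max = 2.0 * np.max(np.abs(Z.T @ (y - y.mean())))
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max * min_ratio), np.log10(lam_max),
                       size)[::-1]


@dataclass
class ForestDeltaBP:
    model: RandomForestRegressor
    feature_names: list

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))


def fit_rf(X: np.ndarray, y: np.ndarray, mtry: int, n_trees: int = 300,
           seed: int = 0, feature_names: list | None = None) -> ForestDeltaBP:
    """Bootstrap regression forest with squared-error splits."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if not (1 <= mtry <= m):
        raise ValueError(f"mtry must be in [1, {m}]")
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, criterion="squared_error",
        bootstrap=True, random_state=int(seed) % (2 ** 31))
    rf.fit(X, np.asarray(y, dtype=float))
    names = feature_names or [f"x{j}" for j in range(m)]
    return ForestDeltaBP(model=rf, feature_names=names)


def mtry_grid(m: int) -> list:
    """Default per-node feature-subsample grid for M features."""
    grid = sorted({max(1, int(np.ceil(m / 10))), max(1, int(np.ceil(m / 3))),
                   max(1, int(np.ceil(m / 2))), m})
    return grid


# ---------------------------------------------------------------------------
# fold bookkeeping


@dataclass
class FoldResult:
    test_participant: object
    t: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    hyperparameter: float
    model: object = None
    selected_features: list = field(default_factory=list)

    @property
    def rho_p(self) -> float:
        if len(self.y_true) < 3:
            return np.nan
        a = self.y_true - self.y_true.mean()
        b = self.y_pred - self.y_pred.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom <= 1e-30:
            return np.nan
        return float(np.clip((a @ b) / denom, -1.0, 1.0))

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean((self.y_true - self.y_pred) ** 2)))

    @property
    def mae(self) -> float:
        return float(np.mean(np.abs(self.y_true - self.y_pred)))


@dataclass
class ComparisonTable:
    frame: pd.DataFrame       # pair, metric, statistic, p, p_adjusted


def _fit_model(kind: str, X, y, hyper, n_trees, seed, names):
    if kind == "lasso_ols":
        return fit_lasso_ols(X, y, hyper, names)
    if kind == "rf":
        return fit_rf(X, y, int(hyper), n_trees, seed, names)
    raise ValueError(f"unknown model kind '{kind}'")


def nested_losocv(dataset: CalibratedDataset, model_kind: str,
                  channel: str = "sbp", feature_set: str = "ppg",
                  hyper_grid=None, n_trees: int = 300, seed: int = 0,
                  lambda_grid_size: int = 30) -> list:
    """Nested leave-one-subject-out cross-validation.

    The outer loop holds out each participant; the inner LOSOCV over the
    remaining participants selects the hyperparameter minimising the mean
    inner RMSE (scored on unaugmented rows, mirroring the outer
    evaluation); the final fold model is trained on all inner augmented
    rows and evaluated on the held-out participant's unaugmented rows.
    """
    pids = np.unique(dataset.participant_ids)
    if len(pids) < 3:
        raise ValueError("nested LOSOCV needs at least 3 participants")
    cols = select_feature_columns(dataset.feature_names, feature_set)
    ycol = f"d{channel}"
    Xall = dataset.X[cols].to_numpy(dtype=float)
    yall = dataset.y[ycol].to_numpy(dtype=float)
    aug = dataset.augmented_mask
    t_all = (dataset.X["t"].to_numpy() if "t" in dataset.X
             else np.arange(len(yall), dtype=float))

    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2 ** 31 - 1, size=len(pids))
    results = []
    for fold, pid in enumerate(pids):
        test = dataset.participant_ids == pid
        if not (test & ~aug).any():
            continue
        train = ~test
        inner_pids = [q for q in pids if q != pid]
        if hyper_grid is None:
            if model_kind == "lasso_ols":
                grid = lambda_grid(Xall[train], yall[train],
                                   size=lambda_grid_size)
            else:
                grid = mtry_grid(len(cols))
        else:
            grid = list(hyper_grid)
        if len(grid) == 1:
            best = grid[0]
        else:
            score = np.full(len(grid), np.nan)
            for g, hyper in enumerate(grid):
                errs = []
                for q in inner_pids:
                    val = dataset.participant_ids == q
                    tr = train & ~val
                    ev = val & ~aug
                    if not ev.any() or not tr.any():
                        continue
                    mod = _fit_model(model_kind, Xall[tr], yall[tr], hyper,
                                     n_trees, fold_seeds[fold], cols)
                    pred = mod.predict(Xall[ev])
                    errs.append(np.sqrt(np.mean((yall[ev] - pred) ** 2)))
                if errs:
                    score[g] = np.mean(errs)
            best = grid[int(np.nanargmin(score))]
        model = _fit_model(model_kind, Xall[train], yall[train], best,
                           n_trees, fold_seeds[fold], cols)
        ev = test & ~aug
        selected = []
        if model_kind == "lasso_ols":
            selected = [c for c, s in zip(cols, model.support) if s]
        results.append(FoldResult(
            test_participant=pid, t=t_all[ev], y_true=yall[ev],
            y_pred=model.predict(Xall[ev]), hyperparameter=float(best),
            model=model, selected_features=selected))
    return results


def baseline_reference(dataset: CalibratedDataset,
                       channel: str = "sbp") -> pd.DataFrame:
    """No-change reference: predict dBP = 0 for every observation.

    The correlation coefficient is undefined for a constant prediction and
    is reported as missing, never zero.
    """
    ycol = f"d{channel}"
    rows = []
    for pid in np.unique(dataset.participant_ids):
        mask = dataset.rows_for(pid) & ~dataset.augmented_mask
        y = dataset.y.loc[mask, ycol].to_numpy(dtype=float)
        rows.append({"participant": pid, "rho_p": np.nan,
                     "rmse": float(np.sqrt(np.mean(y ** 2))),
                     "mae": float(np.mean(np.abs(y)))})
    return pd.DataFrame(rows)


def compare_models(metrics: dict, metric_names=("rho_p", "rmse", "mae"),
                   exact_n: int = 25) -> ComparisonTable:
    """Pairwise two-tailed Wilcoxon signed-rank tests with BH adjustment.

    ``metrics`` maps a model label to a per-participant metric DataFrame
    (participant-aligned).  The exact null distribution is used for n <= 25
    pairs, the normal approximation above.
    """
    labels = list(metrics)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = metrics[labels[i]], metrics[labels[j]]
            merged = a.merge(b, on="participant", suffixes=("_a", "_b"))
            for metric in metric_names:
                xa = merged[f"{metric}_a"].to_numpy(dtype=float)
                xb = merged[f"{metric}_b"].to_numpy(dtype=float)
                ok = np.isfinite(xa) & np.isfinite(xb)
                d = xa[ok] - xb[ok]
                if len(d) == 0 or np.all(d == 0):
                    stat, p = 0.0, 1.0
                else:
                    method = "exact" if len(d) <= exact_n else "approx"
                    res = stats.wilcoxon(d, alternative="two-sided",
                                         method=method)
                    stat, p = float(res.statistic), float(res.pvalue)
                rows.append({"pair": f"{labels[i]} vs {labels[j]}",
                             "metric": metric, "statistic": stat, "p": p})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
    return ComparisonTable(frame=frame)


# ---------------------------------------------------------------------------
# Model / Results front end


class DeltaBPModel:
    """ΔBP estimator specification bound to a calibrated dataset.

    Parameters
    ----------
    dataset : CalibratedDataset
        Assembled cohort dataset (see :mod:`ppgbp.dataset`).
    model_kind : {"lasso_ols", "rf"}
    channel : {"sbp", "map", "dbp"}
    feature_set : {"ppg", "ecg", "ppg+ecg", "pat"}
    """

    def __init__(self, dataset: CalibratedDataset, model_kind: str = "rf",
                 channel: str = "sbp", feature_set: str = "ppg",
                 hyper_grid=None, n_trees: int = 300,
                 lambda_grid_size: int = 30):
        self.dataset = dataset
        self.model_kind = model_kind
        self.channel = channel
        self.feature_set = feature_set
        self.hyper_grid = hyper_grid
        self.n_trees = n_trees
        self.lambda_grid_size = lambda_grid_size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dynamic_features: list,
                       participant_col: str = "participant_id",
                       augmented_col: str | None = "augmented",
                       **kwargs) -> "DeltaBPModel":
        """Build a model from a flat table with dBP targets and features."""
        ycols = [c for c in ("dsbp", "dmap", "ddbp") if c in df.columns]
        demo = [c for c in DEMOGRAPHIC_FEATURES if c in df.columns]
        X = df[[c for c in df.columns
                if c in dynamic_features + demo + ["t"]]].copy()
        y = df[ycols].copy()
        aug = (df[augmented_col].to_numpy(dtype=bool)
               if augmented_col and augmented_col in df
               else np.zeros(len(df), dtype=bool))
        ds = CalibratedDataset(
            X=X, y=y, participant_ids=df[participant_col].to_numpy(),
            augmented_mask=aug, dynamic_features=list(dynamic_features),
            demographic_features=demo)
        return cls(ds, **kwargs)

    def fit(self, seed: int = 0) -> "DeltaBPResults":
        folds = nested_losocv(
            self.dataset, self.model_kind, channel=self.channel,
            feature_set=self.feature_set, hyper_grid=self.hyper_grid,
            n_trees=self.n_trees, seed=seed,
            lambda_grid_size=self.lambda_grid_size)
        return DeltaBPResults(self, folds, seed)


class DeltaBPResults:
    """Nested-LOSOCV estimation results."""

    def __init__(self, model: DeltaBPModel, folds: list, seed: int):
        self.model = model
        self.folds = folds
        self.seed = seed

    # -- metrics ---------------------------------------------------------
    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"participant": f.test_participant, "rho_p": f.rho_p,
             "rmse": f.rmse, "mae": f.mae,
             "hyperparameter": f.hyperparameter}
            for f in self.folds])

    def predictions_frame(self) -> pd.DataFrame:
        parts = []
        for f in self.folds:
            parts.append(pd.DataFrame({
                "participant": f.test_participant, "t": f.t,
                "y_true": f.y_true, "y_pred": f.y_pred}))
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> str:
        mf = self.metrics_frame()
        name = (f"{'RF' if self.model.model_kind == 'rf' else 'LASSO+OLS'}"
                f"_{self.model.feature_set.upper()}")
        lines = [
            f"ΔBP estimation results ({name}, channel={self.model.channel})",
            f"participants (folds): {len(self.folds)}",
            "metric            median      IQR",
        ]
        for metric, unit in (("rho_p", ""), ("rmse", " mmHg"),
                             ("mae", " mmHg")):
            vals = mf[metric].dropna()
            med = vals.median()
            iqr = vals.quantile(0.75) - vals.quantile(0.25)
            lines.append(f"{metric:<12} {med:>12.3f} {iqr:>8.3f}{unit}")
        return "\n".join(lines)

    # -- importance ------------------------------------------------------
    def feature_importance(self, background_size: int = 100,
                           kernel_nsamples: int = 2048,
                           max_rows: int = 200, seed: int | None = None):
        """Per-fold SHAP attributions aggregated into a ranking report."""
        from .importance import fold_importance, ranking_coefficient

        seed = self.seed if seed is None else seed
        per_fold = fold_importance(
            self, background_size=background_size,
            kernel_nsamples=kernel_nsamples, max_rows=max_rows, seed=seed)
        return ranking_coefficient(per_fold)

    # -- plotting --------------------------------------------------------
    def plot_predictions(self, ax=None):
        """Reference-versus-estimate scatter across all held-out folds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for f in self.folds:
            ax.scatter(f.y_true, f.y_pred, s=12, alpha=0.6,
                       label=str(f.test_participant))
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("reference ΔBP (mmHg)")
        ax.set_ylabel("estimated ΔBP (mmHg)")
        ax.set_title(self.model.model_kind)
        return ax
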