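"""Shapley-value feature importance and the fold ranking coefficient.

Attributions phi_j decompose each model prediction into per-feature
contributions around the expected model output phi_0 over a background set
(local accuracy: phi_0 + sum_j phi_j equals the prediction).  Two engines:

* Kernel SHAP — kernel-weighted coalition regression.  Coalitions are
  enumerated exhaustively when feasible and sampled from the Shapley
  kernel otherwise; coalition values are interventional expectations over
  the background set (computed in closed form for linear models).
* Tree SHAP — exact per-tree path algorithm for the interventional game
  against each background sample, averaged over trees and background.

Per fold of the cross-validation, the overall importance of a feature is
its mean absolute SHAP value across the training data; features are ranked
per fold and the rank is normalised to a coefficient in [0, 1] (1 best,
0 worst, average ranks on ties).  Agreement of rankings across BP channels
is quantified with Kendall's tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ShapAttribution", "RankingReport", "kernel_shap", "shap_linear",
    "shap_tree", "fold_importance", "ranking_coefficient", "rank_agreement",
]


@dataclass
class ShapAttribution:
    phi: np.ndarray          # (n_explain, M)
    phi0: float              # expected model value over the background
    feature_names: list

    def local_accuracy_error(self, predictions: np.ndarray) -> np.ndarray:
        return np.abs(self.phi0 + self.phi.sum(axis=1) - predictions)


# ---------------------------------------------------------------------------
# Kernel SHAP


def _kernel_weight(M: int, s: int) -> float:
    return (M - 1) / (comb(M, s) * s * (M - s))


def _coalitions(M: int, nsamples: int, rng: np.random.Generator):
    """Coalition masks and regression weights (enumerated or sampled)."""
    total = 2 ** M - 2
    if total <= nsamples:
        masks = np.zeros((total, M), dtype=bool)
        weights = np.empty(total)
        k = 0
        for code in range(1, 2 ** M - 1):
            bits = np.array([(code >> j) & 1 for j in range(M)], dtype=bool)
            masks[k] = bits
            weights[k] = _kernel_weight(M, int(bits.sum()))
            k += 1
        return masks, weights
    sizes = np.arange(1, M)
    p = np.array([(M - 1) / (s * (M - s)) for s in sizes])
    p /= p.sum()
    drawn = rng.choice(sizes, size=nsamples, p=p)
    masks = np.zeros((nsamples, M), dtype=bool)
    for i, s in enumerate(drawn):
        masks[i, rng.choice(M, size=s, replace=False)] = True
    return masks, np.ones(nsamples)


def _solve(masks: np.ndarray, weights: np.ndarray, v: np.ndarray,
           phi0: float, fx: float) -> np.ndarray:
    """Weighted least squares with the sum constraint eliminated."""
    M = masks.shape[1]
    if M == 1:
        return np.array([fx - phi0])
    z = masks.astype(float)
    A = z[:, :-1] - z[:, -1:][:, [0] * (M - 1)]
    b = (v - phi0) - z[:, -1] * (fx - phi0)
    w = np.sqrt(weights)
    beta, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
    phi = np.empty(M)
    phi[:-1] = beta
    phi[-1] = (fx - phi0) - beta.sum()
    return phi


def kernel_shap(predict, X_background: np.ndarray, X_explain: np.ndarray,
                nsamples: int = 2048, seed: int = 0,
                feature_names: list | None = None) -> ShapAttribution:
    """Kernel SHAP for an arbitrary ``predict`` callable.

    Coalition values are interventional expectations over the background
    set: v(S) = mean_z f(x_S, z_{not S}).
    """
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if len(Xb) == 0:
        raise ValueError("background set must be non-empty")
    M = Xe.shape[1]
    rng = np.random.default_rng(seed)
    phi0 = float(np.mean(predict(Xb)))
    masks, weights = _coalitions(M, nsamples, rng)
    phi = np.empty((len(Xe), M))
    fxs = np.asarray(predict(Xe), dtype=float)
    for i, x in enumerate(Xe):
        v = np.empty(len(masks))
        for k, mask in enumerate(masks):
            hybrid = np.where(mask, x, Xb)
            v[k] = float(np.mean(predict(hybrid)))
        phi[i] = _solve(masks, weights, v, phi0, float(fxs[i]))
    names = feature_names or [f"x{j}" for j in range(M)]
    return ShapAttribution(phi=phi, phi0=phi0, feature_names=names)


def shap_linear(model, X_background: np.ndarray, X_explain: np.ndarray,
                nsamples: int = 2048, seed: int = 0,
                feature_names: list | None = None) -> ShapAttribution:
    """Kernel SHAP for a linear model with a closed-form value oracle.

    For a linear f the interventional coalition value reduces to
    v(S) = b + sum_{j in S} c_j x_j + sum_{j not in S} c_j zbar_j, which
    makes the kernel regression exact and fast at any dimensionality.
    """
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if len(Xb) == 0:
        raise ValueError("background set must be non-empty")
    coef = np.asarray(model.coef, dtype=float)
    M = len(coef)
    rng = np.random.default_rng(seed)
    zbar = Xb.mean(axis=0)
    phi0 = float(coef @ zbar + model.intercept)
    masks, weights = _coalitions(M, nsamples, rng)
    z = masks.astype(float)
    base = float(coef @ zbar)
    phi = np.empty((len(Xe), M))
    for i, x in enumerate(Xe):
        v = model.intercept + base + z @ (coef * (x - zbar))
        fx = float(coef @ x + model.intercept)
        phi[i] = _solve(masks, weights, v, phi0, fx)
    names = feature_names or [f"x{j}" for j in range(M)]
    return ShapAttribution(phi=phi, phi0=phi0, feature_names=names)


# ---------------------------------------------------------------------------
# Tree SHAP (interventional, exact per background sample)


def _w_factor(a: int, b: int) -> float:
    return factorial(a) * factorial(b) / factorial(a + b + 1)


def _tree_arrays(tree):
    t = tree.tree_
    return (t.children_left, t.children_right, t.feature, t.threshold,
            t.value[:, 0, 0])


def _tree_phi_single(arrays, x: np.ndarray, z: np.ndarray,
                     phi: np.ndarray) -> None:
    """Accumulate exact Shapley values of one tree for foreground x against
    a single background sample z."""
    left, right, feature, threshold, value = arrays

    def recurse(node, x_feats, z_feats):
        f = feature[node]
        if f < 0:  # leaf
            v = value[node]
            a, b = len(x_feats), len(z_feats)
            if a:
                w = _w_factor(a - 1, b)
                for j in x_feats:
                    phi[j] += w * v
            if b:
                w = _w_factor(a, b - 1)
                for j in z_feats:
                    phi[j] -= w * v
            return
        x_left = x[f] <= threshold[node]
        z_left = z[f] <= threshold[node]
        if x_left == z_left:
            recurse(left[node] if x_left else right[node], x_feats, z_feats)
        elif f in x_feats:
            recurse(left[node] if x_left else right[node], x_feats, z_feats)
        elif f in z_feats:
            recurse(left[node] if z_left else right[node], x_feats, z_feats)
        else:
            recurse(left[node] if x_left else right[node],
                    x_feats | {f}, z_feats)
            recurse(left[node] if z_left else right[node],
                    x_feats, z_feats | {f})

    recurse(0, frozenset(), frozenset())


def shap_tree(model, X_background: np.ndarray, X_explain: np.ndarray,
              feature_names: list | None = None) -> ShapAttribution:
    """Exact interventional Tree SHAP for a forest (or single tree).

    Shapley values are computed exactly for each (tree, background sample)
    pair by a single traversal that tracks the features on which the
    foreground and background diverge, then averaged (Shapley linearity).
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    est = getattr(model, "model", model)
    if isinstance(est, RandomForestRegressor):
        trees = est.estimators_
    elif isinstance(est, DecisionTreeRegressor):
        trees = [est]
    else:
        raise ValueError("shap_tree expects a random forest or decision tree")
    Xb = np.atleast_2d(np.asarray(X_background, dtype=float))
    Xe = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if len(Xb) == 0:
        raise ValueError("background set must be non-empty")
    M = Xe.shape[1]
    n_f = trees[0].tree_.n_features
    if n_f != M:
        raise ValueError(
            f"feature mismatch: model expects {n_f}, got {M}")
    arrays = [_tree_arrays(t) for t in trees]
    phi = np.zeros((len(Xe), M))
    for i, x in enumerate(Xe):
        acc = np.zeros(M)
        for arr in arrays:
            for z in Xb:
                _tree_phi_single(arr, x, z, acc)
        phi[i] = acc / (len(trees) * len(Xb))
    phi0 = float(np.mean(est.predict(Xb)))
    names = feature_names or [f"x{j}" for j in range(M)]
    return ShapAttribution(phi=phi, phi0=phi0, feature_names=names)


# ---------------------------------------------------------------------------
# ranking


@dataclass
class RankingReport:
    per_fold: pd.DataFrame      # feature, fold, mean_abs_phi, rank, coefficient
    summary: pd.DataFrame       # feature, median/min/max coefficient

    def median_coefficients(self) -> pd.Series:
        return self.summary.set_index("feature")["median"]


def ranking_coefficient(per_fold_importance: list) -> RankingReport:
    """Normalised per-fold ranking coefficients from mean-|phi| importances.

    ``per_fold_importance`` is a list (one entry per fold) of mappings
    feature -> mean absolute SHAP value.  Within each fold features are
    ranked descending (rank 1 best, ties get average ranks) and the rank
    is rescaled to (M - rank) / (M - 1) so the best feature scores 1 and
    the worst 0.
    """
    if len(per_fold_importance) == 0:
        raise ValueError("need at least one fold")
    rows = []
    for fold, imp in enumerate(per_fold_importance):
        ser = pd.Series(imp, dtype=float)
        M = len(ser)
        ranks = ser.rank(ascending=False, method="average")
        coeff = (M - ranks) / (M - 1) if M > 1 else ranks * 0 + 1.0
        for feat in ser.index:
            rows.append({"feature": feat, "fold": fold,
                         "mean_abs_phi": ser[feat], "rank": ranks[feat],
                         "coefficient": coeff[feat]})
    per_fold = pd.DataFrame(rows)
    summary = (per_fold.groupby("feature")["coefficient"]
               .agg(median="median", min="min", max="max").reset_index()
               .sort_values("median", ascending=False)
               .reset_index(drop=True))
    return RankingReport(per_fold=per_fold, summary=summary)


def rank_agreement(report_a: RankingReport,
                   report_b: RankingReport) -> float:
    """Kendall tau-b between two channels' median ranking coefficients."""
    a = report_a.median_coefficients()
    b = report_b.median_coefficients()
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("rankings share no features")
    tau, _ = stats.kendalltau(a[common], b[common])
    return float(tau)


# ---------------------------------------------------------------------------
# per-fold aggregation for DeltaBPResults


def fold_importance(results, background_size: int = 100,
                    kernel_nsamples: int = 2048, max_rows: int = 200,
                    seed: int = 0) -> list:
    """Mean absolute SHAP value per feature on each fold's training data."""
    from .estimation import select_feature_columns

    dataset = results.model.dataset
    cols = select_feature_columns(dataset.feature_names,
                                  results.model.feature_set)
    Xall = dataset.X[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for fres in results.folds:
        train = dataset.participant_ids != fres.test_participant
        Xtr = Xall[train]
        bg_idx = rng.choice(len(Xtr), size=min(background_size, len(Xtr)),
                            replace=False)
        ex_idx = rng.choice(len(Xtr), size=min(max_rows, len(Xtr)),
                            replace=False)
        if results.model.model_kind == "lasso_ols":
            attr = shap_linear(fres.model, Xtr[bg_idx], Xtr[ex_idx],
                               nsamples=kernel_nsamples, seed=seed,
                               feature_names=cols)
        else:
            attr = shap_tree(fres.model, Xtr[bg_idx], Xtr[ex_idx],
                             feature_names=cols)
        out.append(dict(zip(cols, np.mean(np.abs(attr.phi), axis=0))))
    return out
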