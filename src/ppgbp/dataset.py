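"""Regression-dataset assembly.

Feature streams are averaged in windows centred on the reference BP sample
times (40 s by default, only good-quality beats, a window discarded when
more than half of it is bad), conditioned (median/MAD outlier removal, a
scalar random-walk Kalman filter, nearest-neighbour imputation), calibrated
to each participant's rest-period baseline as relative changes

    x_ij = (f_ij - fhat_j) / fhat_j ,   dBP_i = BP_i - BPhat ,

augmented with intermediate rows from the smoothed BP reference (1/15 Hz,
15-s windows), joined with demographics, and finally pruned of collinear
features by iterative variance-inflation-factor removal (VIF > 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEMOGRAPHIC_FEATURES", "CalibratedDataset", "CollinearityReport",
    "window_features", "condition_feature_streams", "calibrate",
    "augmentation_times", "remove_collinear", "vif", "condition_number",
]

DEMOGRAPHIC_FEATURES = ["age", "sex", "height", "weight", "bmi",
                        "bp_calibration"]


@dataclass
class CalibratedDataset:
    """Assembled regression dataset across the cohort."""

    X: pd.DataFrame                    # calibrated features + demographics
    y: pd.DataFrame                    # columns dsbp, dmap, ddbp
    participant_ids: np.ndarray
    augmented_mask: np.ndarray         # True for augmentation-only rows
    dynamic_features: list
    demographic_features: list = field(
        default_factory=lambda: list(DEMOGRAPHIC_FEATURES))
    baselines: dict = field(default_factory=dict)   # pid -> {feature: fhat}

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    def rows_for(self, pid) -> np.ndarray:
        return self.participant_ids == pid


@dataclass
class CollinearityReport:
    removed: list                      # feature names in removal order
    vif_history: list                  # max VIF at each removal step
    condition_before: float
    condition_after: float
    final_vif: dict                    # surviving feature -> VIF


# ---------------------------------------------------------------------------
# windowing


def window_features(stream: pd.DataFrame, centers: np.ndarray, window_s: float,
                    sqi_min: float = 0.8, feature_cols: list | None = None,
                    time_col: str = "t", sqi_col: str = "sqi") -> pd.DataFrame:
    """Average feature values of good-quality rows in windows around centers.

    A window is recorded as missing (NaN) when more than half of the rows
    falling inside it are of bad quality, or when it is empty.
    """
    if feature_cols is None:
        feature_cols = [c for c in stream.columns
                        if c not in (time_col, sqi_col)]
    t = stream[time_col].to_numpy()
    sqi = stream[sqi_col].to_numpy() if sqi_col in stream else np.ones(len(t))
    half = window_s / 2.0
    rows = []
    for tc in np.asarray(centers, dtype=float):
        inside = (t >= tc - half) & (t <= tc + half)
        n_in = int(inside.sum())
        good = inside & (sqi > sqi_min)
        if n_in == 0 or good.sum() <= 0.5 * n_in:
            rows.append({time_col: tc,
                         **{c: np.nan for c in feature_cols}})
            continue
        sub = stream.loc[good, feature_cols]
        rows.append({time_col: tc, **sub.mean().to_dict()})
    return pd.DataFrame(rows, columns=[time_col] + feature_cols)


# ---------------------------------------------------------------------------
# conditioning


def _kalman_random_walk(y: np.ndarray) -> np.ndarray:
    """Scalar random-walk Kalman filter over a (possibly gappy) series.

    Process and measurement variances are apportioned from the variance of
    the stream's first differences; a constant stream passes through
    unchanged.
    """
    obs = np.isfinite(y)
    if obs.sum() < 3:
        return y.copy()
    diffs = np.diff(y[obs])
    v = float(np.var(diffs))
    if v <= 0:
        return y.copy()
    q, r = 0.2 * v, 0.8 * v
    out = y.copy()
    x_est, p_est = None, None
    for i in range(len(y)):
        if not obs[i]:
            if p_est is not None:
                p_est += q
            continue
        if x_est is None:
            x_est, p_est = y[i], r
        else:
            p_pred = p_est + q
            k = p_pred / (p_pred + r)
            x_est = x_est + k * (y[i] - x_est)
            p_est = (1 - k) * p_pred
        out[i] = x_est
    return out


def condition_feature_streams(rows: pd.DataFrame, feature_cols: list,
                              outlier_mad: float = 5.0,
                              outlier_window: int = 10,
                              time_col: str = "t") -> pd.DataFrame:
    """Outlier removal, Kalman smoothing and nearest-neighbour imputation.

    Operates per feature on a single participant's time-ordered window rows.
    A feature with no finite values at all is dropped with a warning.
    """
    out = rows.sort_values(time_col).reset_index(drop=True).copy()
    t = out[time_col].to_numpy()
    drop = []
    for col in feature_cols:
        y = out[col].to_numpy(dtype=float)
        finite = np.isfinite(y)
        if not finite.any():
            logger.warning("feature %s entirely missing; dropped", col)
            drop.append(col)
            continue
        # rolling-median / MAD outlier rejection
        ser = pd.Series(np.where(finite, y, np.nan))
        med = ser.rolling(outlier_window, center=True, min_periods=3).median()
        mad = (ser - med).abs().rolling(outlier_window, center=True,
                                        min_periods=3).median()
        scale = 1.4826 * mad.to_numpy()
        dev = np.abs(y - med.to_numpy())
        with np.errstate(invalid="ignore"):
            is_out = finite & (scale > 0) & (dev > outlier_mad * scale)
        y = np.where(is_out, np.nan, y)
        y = _kalman_random_walk(y)
        # nearest-neighbour imputation in time
        finite = np.isfinite(y)
        if 0 < finite.sum() < len(y):
            idx = np.nonzero(finite)[0]
            nearest = idx[np.argmin(
                np.abs(t[:, None] - t[idx][None, :]), axis=1)]
            y = np.where(finite, y, y[nearest])
        out[col] = y
    return out.drop(columns=drop)


# ---------------------------------------------------------------------------
# calibration


def calibrate(rows: pd.DataFrame, rest_window: tuple, feature_cols: list,
              time_col: str = "t") -> tuple:
    """Relative-change calibration against the rest-period feature means.

    Returns ``(calibrated_rows, baselines)``; a feature whose rest-period
    mean is zero is undefined for the participant and dropped with a
    warning.
    """
    t = rows[time_col].to_numpy()
    in_rest = (t >= rest_window[0]) & (t <= rest_window[1])
    if not in_rest.any():
        raise ValueError("rest window contains no feature rows")
    out = rows.copy()
    baselines = {}
    for col in feature_cols:
        fhat = float(np.nanmean(rows.loc[in_rest, col]))
        if fhat == 0 or not np.isfinite(fhat):
            logger.warning("rest-period mean of %s is zero/undefined; "
                           "feature dropped for participant", col)
            out = out.drop(columns=[col])
            continue
        baselines[col] = fhat
        out[col] = (rows[col] - fhat) / fhat
    return out, baselines


def augmentation_times(t0: float, t1: float, f_aug: float,
                       original: np.ndarray, window_s: float) -> np.ndarray:
    """Augmentation grid inside [t0, t1], excluding original sample times.

    Raises when consecutive grid points are closer than the window length
    (overlapping windows would break the independence assumption).
    """
    step = 1.0 / f_aug
    if step < window_s - 1e-9:
        raise ValueError(
            f"augmentation windows of {window_s}s overlap at {f_aug} Hz")
    n = int(np.floor((t1 - t0) * f_aug + 1e-9)) + 1
    grid = t0 + np.arange(n) * step
    original = np.asarray(original, dtype=float)
    keep = np.array([np.min(np.abs(original - g)) > 1e-6 if len(original)
                     else True for g in grid])
    return grid[keep]


# ---------------------------------------------------------------------------
# collinearity


def vif(X: np.ndarray, j: int) -> float:
    """Variance inflation factor of column j regressed on the others."""
    n = X.shape[0]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(n), others])
    y = X[:, j]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        return np.inf
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def condition_number(X: np.ndarray) -> float:
    """Ratio of extreme singular values of the standardised design."""
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    s = np.linalg.svd(Z, compute_uv=False)
    return float(s[0] / s[-1]) if s[-1] > 0 else np.inf


def remove_collinear(X: pd.DataFrame, dynamic_cols: list | None = None,
                     threshold: float = 10.0) -> tuple:
    """Iteratively drop the feature with the largest VIF until all <= 10.

    Demographic columns are exempt from removal (they are retained for the
    importance analysis); VIF is computed among the dynamic features only.
    Returns ``(X_reduced, CollinearityReport)``.
    """
    if dynamic_cols is None:
        dynamic_cols = [c for c in X.columns if c not in DEMOGRAPHIC_FEATURES]
    cols = list(dynamic_cols)
    if X[cols].isna().any().any():
        raise ValueError("collinearity removal requires complete data")
    cond_before = condition_number(X[cols].to_numpy())
    removed, history = [], []
    while len(cols) > 1:
        mat = X[cols].to_numpy()
        vifs = np.array([vif(mat, j) for j in range(len(cols))])
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        removed.append(cols[worst])
        history.append(float(vifs[worst]))
        if not np.isfinite(vifs[worst]):
            logger.info("perfectly collinear feature %s removed",
                        cols[worst])
        cols.pop(worst)
    mat = X[cols].to_numpy()
    final = {c: float(vif(mat, j)) for j, c in enumerate(cols)}
    keep = cols + [c for c in X.columns if c not in dynamic_cols]
    report = CollinearityReport(
        removed=removed, vif_history=history,
        condition_before=cond_before,
        condition_after=condition_number(X[cols].to_numpy()),
        final_vif=final)
    return X[keep].copy(), report
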