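"""Reference blood pressure from sparse, noisy cuff readings.

The cuff inflates roughly once a minute with dropouts and device noise, so
each channel (SBP / MAP / DBP) is smoothed with a natural cubic smoothing
spline minimising

    p * sum_i (y_i - f(t_i))^2 + integral f''(t)^2 dt

where the penalty weight ``p`` trades residual fit against roughness:
p -> 0 recovers the linear least-squares line, p -> infinity the
interpolating cubic spline.  One common ``p`` per channel is selected for
the whole cohort by a leave-one-out grid search over a log-spaced range.
The minimiser is delegated to scipy's smoothing-spline solver with
lam = 1/p (the same objective up to a positive scale factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

__all__ = ["CuffSeries", "SmoothedBP", "default_p_grid",
           "fit_smoothing_spline", "select_p", "resample", "smooth_recording"]


@dataclass
class CuffSeries:
    """One channel of cuff observations y_i at strictly increasing times t_i."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) != len(self.y):
            raise ValueError("t and y must have equal length")
        if len(self.t) < 2:
            raise ValueError("need at least 2 cuff observations")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("cuff times must be strictly increasing")

    def __len__(self):
        return len(self.t)


@dataclass
class SmoothedBP:
    """Fitted smooth reference function for one channel."""

    spline: object           # callable BSpline
    p_used: float
    t_min: float
    t_max: float

    def __call__(self, t):
        return self.spline(t)


def default_p_grid(lo: float = 1e-3, hi: float = 1e8,
                   size: int = 12) -> np.ndarray:
    """Log-spaced penalty-weight grid (default one point per decade)."""
    return np.logspace(np.log10(lo), np.log10(hi), size)


def fit_smoothing_spline(series: CuffSeries, p: float) -> SmoothedBP:
    """Fit the penalised cubic smoothing spline at penalty weight ``p``."""
    if p <= 0:
        raise ValueError("p must be positive")
    if len(np.unique(series.t)) != len(series.t):
        raise ValueError("duplicate cuff times")
    spline = make_smoothing_spline(series.t, series.y, lam=1.0 / p)
    return SmoothedBP(spline=spline, p_used=float(p),
                      t_min=float(series.t[0]), t_max=float(series.t[-1]))


def _loo_rmse(series: CuffSeries, p: float) -> float:
    """Leave-one-out RMSE of spline predictions at the left-out times."""
    n = len(series)
    errs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sub = CuffSeries(series.t[mask], series.y[mask])
        fit = fit_smoothing_spline(sub, p)
        errs[i] = series.y[i] - fit(series.t[i])
    return float(np.sqrt(np.mean(errs ** 2)))


def select_p(cohort: list, grid: np.ndarray | None = None) -> float:
    """Choose the penalty weight minimising participant-wise mean LOO RMSE.

    ``cohort`` is a list of :class:`CuffSeries` (one per participant).
    Participants with fewer than 4 observations are excluded from a
    candidate's average; candidates where every fit fails are dropped.
    """
    grid = default_p_grid() if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("p grid must be non-empty")
    mean_err = np.full(len(grid), np.inf)
    for k, p in enumerate(grid):
        errs = []
        for series in cohort:
            if len(series) < 4:
                logger.info("participant with %d cuff readings excluded "
                            "from LOO at p=%g", len(series), p)
                continue
            try:
                errs.append(_loo_rmse(series, p))
            except Exception as exc:  # singular fit at extreme p
                logger.warning("LOO fit failed at p=%g: %s", p, exc)
                errs = []
                break
        if errs:
            mean_err[k] = np.mean(errs)
    if not np.isfinite(mean_err).any():
        raise ValueError("all penalty candidates failed")
    return float(grid[int(np.argmin(mean_err))])


def resample(smoothed: SmoothedBP, f_bp: float, span: tuple) -> np.ndarray:
    """Evaluate the smooth reference on a regular grid (no extrapolation).

    Returns an array of (t, value) rows; endpoints inclusive.
    """
    t0, t1 = span
    if t0 < smoothed.t_min - 1e-9 or t1 > smoothed.t_max + 1e-9:
        raise ValueError(
            f"requested span [{t0}, {t1}] extends beyond the cuff data "
            f"support [{smoothed.t_min}, {smoothed.t_max}]")
    n = int(np.floor((t1 - t0) * f_bp + 1e-9)) + 1
    t = t0 + np.arange(n) / f_bp
    return np.column_stack([t, smoothed(t)])


def smooth_recording(cuff_events, p_by_channel: dict) -> dict:
    """Smooth all three channels of one participant's cuff DataFrame."""
    out = {}
    for channel in ("sbp", "map", "dbp"):
        series = CuffSeries(cuff_events["t"].to_numpy(),
                            cuff_events[channel].to_numpy())
        out[channel] = fit_smoothing_spline(series, p_by_channel[channel])
    return out
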