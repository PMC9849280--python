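"""ECG complexity and entropy features.

Ten dimensionless descriptors per analysis window of the filtered ECG
waveform: Hjorth mobility and complexity (mean frequency / bandwidth
estimates), Higuchi fractal dimension (k_max = 17), Shannon entropy of the
amplitude histogram, approximate and sample entropy, and multiscale sample
entropy at coarse-graining scales 2, 4, 6 and 8.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ECG_FEATURES", "hjorth", "higuchi_fd", "shannon_entropy",
           "approx_entropy", "sample_entropy", "coarse_grain",
           "sampen_family", "window_features"]

ECG_FEATURES = ["hjorth_mobility", "hjorth_complexity", "fractal_dimension",
                "shannon_entropy", "approx_entropy", "sample_entropy",
                "mse_2", "mse_4", "mse_6", "mse_8"]


def hjorth(x: np.ndarray):
    """Hjorth mobility and complexity from first differences."""
    x = np.asarray(x, dtype=float)
    dx = np.diff(x)
    v0, v1 = np.var(x), np.var(dx)
    if v0 <= 0 or v1 <= 0:
        return np.nan, np.nan
    mobility = float(np.sqrt(v1 / v0))
    v2 = np.var(np.diff(dx))
    if v2 <= 0:
        return mobility, np.nan
    complexity = float(np.sqrt(v2 / v1) / mobility)
    return mobility, complexity


def higuchi_fd(x: np.ndarray, k_max: int = 17) -> float:
    """Higuchi fractal dimension: slope of log L(k) against log(1/k)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * k_max or np.ptp(x) <= 0:
        return np.nan
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, k_max + 1)
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Shannon entropy (bits) of the amplitude histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _template_counts(x: np.ndarray, dim: int, r: float,
                     n_templates: int) -> np.ndarray:
    """Per-template Chebyshev match counts (self-matches included).

    Uses the shifted-diagonal identity: templates i and j of length ``dim``
    match iff |x[i+k] - x[j+k]| <= r for every k < dim, which is an AND of
    shifted slices of the single pairwise n x n comparison matrix.
    """
    base = np.abs(x[:, None] - x[None, :]) <= r
    acc = base[:n_templates, :n_templates].copy()
    for k in range(1, dim):
        acc &= base[k:k + n_templates, k:k + n_templates]
    return acc.sum(axis=1).astype(float)


def approx_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (self-comparisons included)."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if np.std(x) <= 0:
        return 0.0
    n = len(x)
    if n < m + 2:
        return np.nan
    cm = _template_counts(x, m, r, n - m + 1)
    cm1 = _template_counts(x, m + 1, r, n - m)
    phi_m = np.mean(np.log(cm / (n - m + 1)))
    phi_m1 = np.mean(np.log(cm1 / (n - m)))
    return float(phi_m - phi_m1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) over N - m templates, no self-comparisons.

    Returns NaN (not infinity) when no template matches exist at tolerance r.
    """
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x)
    if np.std(x) <= 0:
        return 0.0
    n = len(x)
    if n < m + 2:
        return np.nan
    b = float(np.sum(_template_counts(x, m, r, n - m)) - (n - m))
    a = float(np.sum(_template_counts(x, m + 1, r, n - m)) - (n - m))
    if a <= 0 or b <= 0:
        return np.nan
    return float(-np.log(a / b))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of ``scale`` consecutive samples."""
    x = np.asarray(x, dtype=float)
    n = (len(x) // scale) * scale
    return x[:n].reshape(-1, scale).mean(axis=1)


def sampen_family(x: np.ndarray, m: int = 2, r_frac: float = 0.2,
                  scales: tuple = (2, 4, 6, 8)) -> dict:
    """ApEn, SampEn and multiscale SampEn with r = r_frac * SD(window)."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x)
    r = r_frac * sd
    out = {
        "approx_entropy": approx_entropy(x, m, r),
        "sample_entropy": sample_entropy(x, m, r),
    }
    for s in scales:
        cg = coarse_grain(x, s)
        out[f"mse_{s}"] = (sample_entropy(cg, m, r)
                           if len(cg) >= 50 else np.nan)
    return out


def window_features(x: np.ndarray, fs: float, decimate: int = 4,
                    m: int = 2, r_frac: float = 0.2, k_max: int = 17,
                    n_bins: int = 16, scales: tuple = (2, 4, 6, 8)) -> dict:
    """All ten ECG features for one window of the filtered waveform.

    The window is decimated before the O(n^2) entropy computations to keep
    runtime bounded; Hjorth and fractal descriptors use the full rate.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * fs:
        return {name: np.nan for name in ECG_FEATURES}
    mob, comp = hjorth(x)
    out = {
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "fractal_dimension": higuchi_fd(x, k_max),
        "shannon_entropy": shannon_entropy(x, n_bins),
    }
    xd = x[::decimate] if decimate > 1 else x
    out.update(sampen_family(xd, m, r_frac, scales))
    return out
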