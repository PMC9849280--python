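"""The PPG feature library: 61 named per-beat features.

Five families:

* PPG morphology (19): notch/diastolic amplitudes, timing intervals,
  systolic/diastolic areas, widths, the pressure index, harmonic measures,
  and distribution shape (skewness, kurtosis);
* VPG morphology (4): mean and variance of the velocity plethysmogram in
  the systolic and diastolic phases;
* APG morphology (8): the a-e wave amplitude ratios, ageing index, b-c and
  b-d slopes, and the APG-timed augmentation index;
* Gaussian decomposition (21): the 12 fitted parameters plus derived
  stiffness indices (augmentation/reflection indices, reflected-wave
  transit time, LVET approximation, systolic/diastolic area ratio, and
  the fourth-wave amplitude and width ratios);
* PCA (9): projections of the PPG, VPG and APG beats onto the first three
  cohort principal components.

Missing fiducials propagate NaN feature values, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, stats

from .fiducials import FiducialSet
from .gaussian import GaussFit, components
from .preprocessing import NormalizedBeat

__all__ = [
    "PPG_MORPHOLOGY_FEATURES", "VPG_FEATURES", "APG_FEATURES",
    "GAUSSIAN_FEATURES", "PCA_FEATURES", "ALL_PPG_FEATURES",
    "morphology_features", "apg_features", "gaussian_features",
    "PcaBasis", "fit_pca_basis", "pca_features", "beat_features",
]

PPG_MORPHOLOGY_FEATURES = [
    "N_amp", "RI", "delta_T", "CT", "T_Sys", "T_Dia", "T_Ratio", "STT",
    "sVRI", "A1", "A2", "IPA", "Width25", "Width50", "PI", "NHA", "IHAR",
    "skewness", "kurtosis",
]
VPG_FEATURES = ["Sys_mu", "Sys_sigma", "Dia_mu", "Dia_sigma"]
APG_FEATURES = ["b_a", "c_a", "d_a", "e_a", "AGI", "slope_bc", "slope_bd",
                "PPG_AI"]
GAUSSIAN_FEATURES = [
    "A_g1", "A_g2", "A_g3", "A_g4",
    "mu_g1", "mu_g2", "mu_g3", "mu_g4",
    "sigma_g1", "sigma_g2", "sigma_g3", "sigma_g4",
    "GaussAI", "GaussRI", "GaussRTT", "GaussAI_R", "GaussRI_R", "GaussLVET",
    "Gauss_Sys_Dias", "Gauss_A4_A1", "Gauss_sigma4_A1",
]
PCA_FEATURES = ["PPG_PCA1", "PPG_PCA2", "PPG_PCA3",
                "VPG_PCA1", "VPG_PCA2", "VPG_PCA3",
                "APG_PCA1", "APG_PCA2", "APG_PCA3"]
ALL_PPG_FEATURES = (PPG_MORPHOLOGY_FEATURES + VPG_FEATURES + APG_FEATURES
                    + GAUSSIAN_FEATURES + PCA_FEATURES)


def _width_at(zeta: np.ndarray, t: np.ndarray, level: float) -> float:
    """Pulse width at a fractional amplitude, linearly interpolated."""
    above = zeta >= level
    if not above.any():
        return np.nan
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    t0 = t[i0]
    if i0 > 0:
        t0 = np.interp(level, [zeta[i0 - 1], zeta[i0]], [t[i0 - 1], t[i0]])
    t1 = t[i1]
    if i1 < len(zeta) - 1 and zeta[i1 + 1] < zeta[i1]:
        t1 = np.interp(level, [zeta[i1 + 1], zeta[i1]], [t[i1 + 1], t[i1]])
    return float(t1 - t0)


def morphology_features(beat: NormalizedBeat, fid: FiducialSet,
                        height_cm: float, nha_harmonics: int = 10) -> dict:
    """PPG (19) and VPG (4) morphology features for one beat."""
    zeta, vpg, t = beat.zeta, beat.vpg, beat.t
    out = {name: np.nan for name in PPG_MORPHOLOGY_FEATURES + VPG_FEATURES}

    s_ok = fid.is_valid("S")
    n_ok = fid.is_valid("N")
    d_ok = fid.is_valid("D")

    if s_ok:
        out["CT"] = fid.t_S
        if fid.t_S > 0:
            out["STT"] = fid.amp_S / fid.t_S
    if n_ok:
        out["N_amp"] = fid.amp_N
        out["T_Sys"] = fid.t_N
        out["T_Dia"] = 1.0 - fid.t_N
        if out["T_Dia"] > 0:
            out["T_Ratio"] = out["T_Sys"] / out["T_Dia"]
        i_N = int(round(fid.t_N * (len(zeta) - 1)))
        if i_N >= 1:
            out["A1"] = float(np.trapezoid(zeta[:i_N + 1], t[:i_N + 1]))
            out["A2"] = float(np.trapezoid(zeta[i_N:], t[i_N:]))
            if out["A1"] > 0:
                out["IPA"] = out["A2"] / out["A1"]
            mu_sys = float(np.mean(zeta[:i_N + 1]))
            mu_dia = float(np.mean(zeta[i_N:]))
            if mu_sys != 0:
                out["sVRI"] = mu_dia / mu_sys
            out["Sys_mu"] = float(np.mean(vpg[:i_N + 1]))
            out["Sys_sigma"] = float(np.var(vpg[:i_N + 1]))
            out["Dia_mu"] = float(np.mean(vpg[i_N:]))
            out["Dia_sigma"] = float(np.var(vpg[i_N:]))
    if d_ok:
        out["RI"] = fid.amp_D
        if s_ok:
            out["delta_T"] = fid.t_D - fid.t_S
    if s_ok and n_ok and fid.is_valid("W"):
        denom = fid.t_N - fid.t_W
        if denom > 0:
            out["PI"] = (fid.t_N - fid.t_S) / denom * height_cm

    out["Width25"] = _width_at(zeta, t, 0.25)
    out["Width50"] = _width_at(zeta, t, 0.50)

    # harmonic content of the beat's own fundamental (1 / beat duration)
    spec = np.abs(np.fft.rfft(zeta - zeta.mean())) ** 2
    n_h = min(nha_harmonics, len(spec) - 1)
    if n_h >= 2:
        total = float(spec[1:n_h + 1].sum())
        if total > 0:
            out["NHA"] = float(spec[2:n_h + 1].sum()) / total
            if np.isfinite(out.get("IPA", np.nan)) and out["IPA"] != 0:
                out["IHAR"] = (1.0 - out["NHA"]) / out["IPA"]

    out["skewness"] = float(stats.skew(zeta))
    out["kurtosis"] = float(stats.kurtosis(zeta, fisher=False))
    return out


def apg_features(fid: FiducialSet, beat: NormalizedBeat) -> dict:
    """APG wave-ratio features; missing waves propagate NaN."""
    out = {name: np.nan for name in APG_FEATURES}
    amps, times = fid.apg_amps, fid.apg_times
    if "a" not in amps or amps["a"] == 0:
        return out
    a = amps["a"]
    for w in "bcde":
        if w in amps:
            out[f"{w}_a"] = amps[w] / a
    if all(w in amps for w in "bcde"):
        out["AGI"] = (amps["b"] - amps["c"] - amps["d"] - amps["e"]) / a
    if "b" in amps and "c" in amps and times["c"] != times["b"]:
        out["slope_bc"] = ((amps["c"] - amps["b"])
                           / (times["c"] - times["b"]) / a)
    if "b" in amps and "d" in amps and times["d"] != times["b"]:
        out["slope_bd"] = ((amps["d"] - amps["b"])
                           / (times["d"] - times["b"]) / a)
    if "b" in times and "d" in times:
        zeta, t = beat.zeta, beat.t
        z_d = float(np.interp(times["d"], t, zeta))
        z_b = float(np.interp(times["b"], t, zeta))
        if z_b != 0:
            out["PPG_AI"] = z_d / z_b
    return out


def gaussian_features(fit: GaussFit, grid_size: int = 400,
                      lvet_frac: float = 0.01) -> dict:
    """The 21 Gaussian-decomposition features.

    Areas are quadratures on the unit interval.  The reflection index is the
    systolic-component area minus the third-wave area; LVET is approximated
    as the time at which the systolic component decays below ``lvet_frac``
    of its maximum after its peak.
    """
    out = {name: np.nan for name in GAUSSIAN_FEATURES}
    if not fit.converged:
        return out
    A, mu, sig = fit.amplitudes, fit.means, fit.widths
    for i in range(4):
        out[f"A_g{i + 1}"] = float(A[i])
        out[f"mu_g{i + 1}"] = float(mu[i])
        out[f"sigma_g{i + 1}"] = float(sig[i])
    t = np.linspace(0.0, 1.0, grid_size)
    comp = components(fit, t)
    area = {k: float(np.trapezoid(v, t)) for k, v in comp.items()}
    out["GaussAI"] = float(comp["g_s"].max() - A[2])
    out["GaussRI"] = area["g_s"] - area["g3"]
    out["GaussRTT"] = float(mu[2] - mu[0])
    if A[0] > 0:
        out["GaussAI_R"] = float((A[0] - A[1]) / A[0])
        out["GaussRI_R"] = float(A[2] / A[0])
        out["Gauss_A4_A1"] = float(A[3] / A[0])
        out["Gauss_sigma4_A1"] = float(sig[3] / A[0])
    if area["g_d"] > 0:
        out["Gauss_Sys_Dias"] = area["g_s"] / area["g_d"]
    gs = comp["g_s"]
    pk = int(np.argmax(gs))
    below = np.nonzero(gs[pk:] < lvet_frac * gs[pk])[0]
    out["GaussLVET"] = float(t[pk + below[0]]) if len(below) else 1.0
    return out


# ---------------------------------------------------------------------------
# PCA features


@dataclass
class PcaBasis:
    """Per-signal mean beat + top eigenvectors of the pooled covariance."""

    mean: dict                 # signal -> (n_samples,) mean beat
    eigenvectors: dict         # signal -> (k, n_samples) orthonormal rows
    explained: dict            # signal -> (k,) explained-variance fractions


def _resample_100(x: np.ndarray, n: int = 100) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, len(x))
    return interpolate.CubicSpline(grid, x)(np.linspace(0.0, 1.0, n))


def fit_pca_basis(beats: list, sqi_threshold: float = 0.8,
                  n_components: int = 3, min_beats: int = 10) -> PcaBasis:
    """PCA of pooled good-quality beats for PPG, VPG and APG.

    Beats are resampled to 100 samples, pooled, mean-normalised, and the
    eigenvectors of the covariance matrix with the largest eigenvalues are
    retained.  Sign convention: the largest-magnitude loading is positive.
    """
    good = [b for b in beats if b.sqi > sqi_threshold]
    if len(good) < min_beats:
        raise ValueError(
            f"need at least {min_beats} good-quality beats, got {len(good)}")
    mean, vecs, expl = {}, {}, {}
    for key, attr in (("ppg", "zeta"), ("vpg", "vpg"), ("apg", "apg")):
        mat = np.stack([_resample_100(getattr(b, attr)) for b in good])
        mu = mat.mean(axis=0)
        centered = mat - mu
        total_var = float(np.sum(centered ** 2))
        if total_var <= 1e-20:
            raise ValueError(
                f"zero variance in pooled {key} beats; PCA undefined")
        # SVD of the centred matrix == eigendecomposition of the covariance
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        k = min(n_components, len(s))
        v = vt[:k]
        for row in range(k):
            j = int(np.argmax(np.abs(v[row])))
            if v[row, j] < 0:
                v[row] = -v[row]
        mean[key] = mu
        vecs[key] = v
        expl[key] = (s[:k] ** 2) / (s ** 2).sum()
    return PcaBasis(mean=mean, eigenvectors=vecs, explained=expl)


def pca_features(beat: NormalizedBeat, basis: PcaBasis) -> dict:
    """Projections of one beat onto the basis eigenvectors (9 features)."""
    out = {}
    for key, attr, prefix in (("ppg", "zeta", "PPG"), ("vpg", "vpg", "VPG"),
                              ("apg", "apg", "APG")):
        x = _resample_100(getattr(beat, attr)) - basis.mean[key]
        proj = basis.eigenvectors[key] @ x
        for i in range(basis.eigenvectors[key].shape[0]):
            out[f"{prefix}_PCA{i + 1}"] = float(proj[i])
    return out


def beat_features(beat: NormalizedBeat, fid: FiducialSet, fit: GaussFit,
                  height_cm: float, basis: PcaBasis | None = None,
                  nha_harmonics: int = 10) -> dict:
    """All 61 PPG-derived features for one beat (52 without a PCA basis)."""
    out = morphology_features(beat, fid, height_cm, nha_harmonics)
    out.update(apg_features(fid, beat))
    out.update(gaussian_features(fit))
    if basis is not None:
        out.update(pca_features(beat, basis))
    return out
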