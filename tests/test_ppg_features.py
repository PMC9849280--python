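"""PPG feature library: morphology, APG, Gaussian and PCA features."""

import numpy as np
import pytest

from ppgbp.fiducials import FiducialSet, detect_fiducials
from ppgbp.gaussian import GaussFit, components, fit_beat
from ppgbp.ppg_features import (ALL_PPG_FEATURES, APG_FEATURES,
                                GAUSSIAN_FEATURES, PCA_FEATURES,
                                PPG_MORPHOLOGY_FEATURES, VPG_FEATURES,
                                apg_features, beat_features, fit_pca_basis,
                                gaussian_features, morphology_features,
                                pca_features)
from ppgbp.preprocessing import NormalizedBeat
from ppgbp.synthetic import beat_parameters

from conftest import model_beat, normalized_model_beat


def _beat(zeta):
    z = np.asarray(zeta, dtype=float)
    return NormalizedBeat(zeta=z, vpg=np.gradient(z, 1.0 / (len(z) - 1)),
                          apg=np.zeros_like(z), onset_time=0.0, duration=1.0)


class TestFeatureCounts:
    def test_ppg_block_has_61_features(self):
        assert len(ALL_PPG_FEATURES) == 61
        assert len(set(ALL_PPG_FEATURES)) == 61
        assert len(PPG_MORPHOLOGY_FEATURES) == 19
        assert len(VPG_FEATURES) == 4
        assert len(APG_FEATURES) == 8
        assert len(GAUSSIAN_FEATURES) == 21
        assert len(PCA_FEATURES) == 9

    def test_beat_features_emits_all_names(self):
        beat = model_beat(0.2, n=200)
        fid = detect_fiducials(beat)
        fit = fit_beat(beat)
        basis = fit_pca_basis(
            [normalized_model_beat(s) for s in np.linspace(0, 1, 12)],
            sqi_threshold=0.5)
        feats = beat_features(beat, fid, fit, 170.0, basis)
        assert set(feats) == set(ALL_PPG_FEATURES)


class TestMorphology:
    def test_triangle_pulse_timing_geometry(self):
        n = 201
        t = np.linspace(0, 1, n)
        zeta = np.interp(t, [0, 0.5, 1.0], [0, 1.0, 0.0])
        beat = _beat(zeta)
        fid = FiducialSet(t_S=0.5, amp_S=1.0, t_N=0.75, amp_N=0.25,
                          t_W=0.25, valid={"S": True, "N": True, "W": True,
                                           "D": False})
        out = morphology_features(beat, fid, height_cm=170.0)
        assert out["T_Sys"] == pytest.approx(0.75)
        assert out["T_Dia"] == pytest.approx(0.25)
        assert out["T_Ratio"] == pytest.approx(3.0)
        assert out["T_Sys"] + out["T_Dia"] == pytest.approx(1.0, abs=1e-9)
        assert out["CT"] == pytest.approx(0.5)
        assert out["STT"] == pytest.approx(2.0)        # amp_S / t_S
        # notch-dependent features exist; D-dependent ones are missing
        assert np.isnan(out["RI"]) and np.isnan(out["delta_T"])
        # PI = (t_N - t_S)/(t_N - t_W) * h
        assert out["PI"] == pytest.approx((0.25 / 0.5) * 170.0)

    def test_single_lobe_sinusoid_nha_zero(self):
        t = np.linspace(0, 1, 100, endpoint=False)
        beat = _beat(0.5 - 0.5 * np.cos(2 * np.pi * t))
        fid = FiducialSet(valid={"S": False})
        out = morphology_features(beat, fid, 170.0)
        assert out["NHA"] == pytest.approx(0.0, abs=1e-12)

    def test_areas_match_quadrature_oracle(self):
        beat = model_beat(0.0, n=200)
        fid = detect_fiducials(beat)
        out = morphology_features(beat, fid, 170.0)
        i_N = int(round(fid.t_N * 199))
        a1 = np.trapezoid(beat.zeta[:i_N + 1], beat.t[:i_N + 1])
        a2 = np.trapezoid(beat.zeta[i_N:], beat.t[i_N:])
        assert out["A1"] == pytest.approx(a1, rel=0.005)
        assert out["A2"] == pytest.approx(a2, rel=0.005)
        assert out["IPA"] == pytest.approx(a2 / a1, rel=0.005)

    def test_invalid_notch_propagates_nan(self):
        beat = model_beat(0.0, n=200)
        fid = FiducialSet(t_S=0.3, amp_S=1.0,
                          valid={"S": True, "N": False, "D": False,
                                 "W": False})
        out = morphology_features(beat, fid, 170.0)
        for name in ("N_amp", "T_Sys", "T_Dia", "T_Ratio", "A1", "A2",
                     "IPA", "sVRI"):
            assert np.isnan(out[name])

    def test_width_levels(self):
        t = np.linspace(0, 1, 1001)
        beat = _beat(np.interp(t, [0, 0.5, 1.0], [0, 1.0, 0.0]))
        fid = FiducialSet(valid={"S": False})
        out = morphology_features(beat, fid, 170.0)
        assert out["Width50"] == pytest.approx(0.5, abs=1e-3)
        assert out["Width25"] == pytest.approx(0.75, abs=1e-3)


class TestApgFeatures:
    def _fid(self, amps, times=None):
        fid = FiducialSet()
        fid.apg_amps = amps
        fid.apg_times = times or {w: 0.1 * (i + 1)
                                  for i, w in enumerate("abcde")}
        fid.valid = {w: w in amps for w in "abcde"}
        return fid

    def test_agi_direct_arithmetic(self):
        fid = self._fid({"a": 2.0, "b": -1.0, "c": 0.5, "d": -0.25,
                         "e": 0.1})
        out = apg_features(fid, model_beat(0.0))
        assert out["AGI"] == pytest.approx((-1.0 - 0.5 + 0.25 - 0.1) / 2.0)
        assert out["b_a"] == pytest.approx(-0.5)
        assert out["e_a"] == pytest.approx(0.05)

    def test_equal_b_c_zero_slope(self):
        fid = self._fid({"a": 1.0, "b": -0.4, "c": -0.4, "d": 0.1,
                         "e": 0.05})
        out = apg_features(fid, model_beat(0.0))
        assert out["slope_bc"] == pytest.approx(0.0)

    def test_ppg_ai_unity_when_amplitudes_equal(self):
        beat = _beat(np.full(100, 0.5))
        fid = self._fid({"a": 1.0, "b": -0.5, "d": -0.2},
                        times={"a": 0.1, "b": 0.2, "d": 0.4})
        out = apg_features(fid, beat)
        assert out["PPG_AI"] == pytest.approx(1.0)

    def test_missing_wave_propagates(self):
        fid = self._fid({"a": 1.0, "b": -0.5})
        out = apg_features(fid, model_beat(0.0))
        assert np.isnan(out["AGI"]) and np.isnan(out["slope_bd"])


class TestGaussianFeatures:
    def test_equal_amplitudes_zero_augmentation(self):
        theta = np.array([[0.5, 0.2, 0.05], [0.5, 0.4, 0.05],
                          [0.3, 0.6, 0.05], [0.2, 0.8, 0.05]])
        out = gaussian_features(GaussFit(theta, 0.0, True))
        assert out["GaussAI_R"] == pytest.approx(0.0)

    def test_rtt_is_mean_difference(self):
        theta = np.array([[0.5, 0.2, 0.05], [0.5, 0.4, 0.05],
                          [0.3, 0.6, 0.05], [0.2, 0.8, 0.05]])
        out = gaussian_features(GaussFit(theta, 0.0, True))
        assert out["GaussRTT"] == pytest.approx(0.4)

    def test_sys_dias_ratio_matches_quadrature(self):
        theta = beat_parameters(0.5)
        fit = GaussFit(theta, 0.0, True)
        out = gaussian_features(fit)
        t = np.linspace(0, 1, 5000)
        comp = components(fit, t)
        oracle = (np.trapezoid(comp["g_s"], t)
                  / np.trapezoid(comp["g_d"], t))
        assert out["Gauss_Sys_Dias"] == pytest.approx(oracle, rel=0.01)

    def test_reflection_index_as_printed(self):
        theta = beat_parameters(0.2)
        fit = GaussFit(theta, 0.0, True)
        out = gaussian_features(fit)
        t = np.linspace(0, 1, 400)
        comp = components(fit, t)
        expect = np.trapezoid(comp["g_s"], t) - np.trapezoid(comp["g3"], t)
        assert out["GaussRI"] == pytest.approx(expect, rel=1e-9)

    def test_unconverged_fit_all_nan(self):
        out = gaussian_features(GaussFit(beat_parameters(0), np.inf, False))
        assert all(np.isnan(v) for v in out.values())


class TestPca:
    def _ensemble(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 100)
        mean = np.exp(-((t - 0.35) ** 2) / 0.02)
        c1 = np.sin(2 * np.pi * t)
        c2 = np.cos(2 * np.pi * t)
        beats = []
        for _ in range(n):
            z = mean + rng.normal(0, 1) * 0.2 * c1 + rng.normal(0, 1) * 0.1 * c2
            beats.append(NormalizedBeat(zeta=z, vpg=z.copy(), apg=z.copy(),
                                        onset_time=0.0, duration=1.0))
        return beats, c1, c2

    def test_recovers_constructed_subspace(self):
        beats, c1, c2 = self._ensemble()
        basis = fit_pca_basis(beats, sqi_threshold=0.5, n_components=2)
        V = basis.eigenvectors["ppg"]
        # principal angle between span(V) and span(c1, c2) below 1 degree
        A = np.linalg.qr(np.column_stack([c1, c2]))[0]
        B = np.linalg.qr(V.T)[0]
        s = np.linalg.svd(A.T @ B, compute_uv=False)
        angle_deg = np.degrees(np.arccos(np.clip(s.min(), -1, 1)))
        assert angle_deg < 1.0

    def test_identical_beats_error(self):
        z = np.linspace(0, 1, 100)
        beats = [NormalizedBeat(zeta=z.copy(), vpg=z.copy(), apg=z.copy(),
                                onset_time=0.0, duration=1.0)
                 for _ in range(15)]
        with pytest.raises(ValueError):
            fit_pca_basis(beats, sqi_threshold=0.5)

    def test_too_few_beats_error(self):
        beats, _, _ = self._ensemble(n=5)
        with pytest.raises(ValueError):
            fit_pca_basis(beats, sqi_threshold=0.5)

    def test_explained_fractions_descending_and_bounded(self):
        beats, _, _ = self._ensemble()
        basis = fit_pca_basis(beats, sqi_threshold=0.5)
        for key in ("ppg", "vpg", "apg"):
            e = basis.explained[key]
            assert np.all(np.diff(e) <= 1e-12)
            assert e.sum() <= 1.0 + 1e-9
        # eigenvectors orthonormal
        V = basis.eigenvectors["ppg"]
        assert np.allclose(V @ V.T, np.eye(len(V)), atol=1e-9)

    def test_projection_identities(self):
        beats, _, _ = self._ensemble()
        basis = fit_pca_basis(beats, sqi_threshold=0.5)
        mean_beat = NormalizedBeat(
            zeta=basis.mean["ppg"].copy(), vpg=basis.mean["vpg"].copy(),
            apg=basis.mean["apg"].copy(), onset_time=0.0, duration=1.0)
        out = pca_features(mean_beat, basis)
        for v in out.values():
            assert v == pytest.approx(0.0, abs=1e-9)
        shifted = NormalizedBeat(
            zeta=basis.mean["ppg"] + 2.0 * basis.eigenvectors["ppg"][0],
            vpg=basis.mean["vpg"].copy(), apg=basis.mean["apg"].copy(),
            onset_time=0.0, duration=1.0)
        out = pca_features(shifted, basis)
        assert out["PPG_PCA1"] == pytest.approx(2.0, abs=1e-9)
        assert out["PPG_PCA2"] == pytest.approx(0.0, abs=1e-9)
        assert out["PPG_PCA3"] == pytest.approx(0.0, abs=1e-9)

    def test_projections_match_dot_product_oracle(self):
        beats, _, _ = self._ensemble()
        basis = fit_pca_basis(beats, sqi_threshold=0.5)
        beat = beats[7]
        out = pca_features(beat, basis)
        x = beat.zeta - basis.mean["ppg"]
        for i in range(3):
            oracle = float(np.dot(basis.eigenvectors["ppg"][i], x))
            assert out[f"PPG_PCA{i + 1}"] == pytest.approx(oracle, abs=1e-9)
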