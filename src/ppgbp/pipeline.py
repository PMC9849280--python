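"""End-to-end orchestration: generate -> preprocess -> features -> reference
-> dataset -> estimate -> explain.

Every stage persists its artifacts in the run directory, and a manifest
records the configuration and seeds, so a rerun with the same config
reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bp_reference, dataset as ds, ecg_features, estimation
from .config import PipelineConfig
from .fiducials import detect_fiducials
from .gaussian import fit_beat_sequence, gate_quality
from .ppg_features import ALL_PPG_FEATURES, beat_features, fit_pca_basis
from .preprocessing import compute_pat, detect_qrs, filter_ecg, filter_ppg, \
    segment_beats
from .synthetic import generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["ParticipantFeatures", "extract_features", "build_dataset",
           "run_pipeline"]


@dataclass
class ParticipantFeatures:
    participant_id: str
    demographics: dict
    ppg_stream: pd.DataFrame        # per-beat features, t + sqi columns
    pat_stream: pd.DataFrame        # t, sqi, PAT
    ecg_filtered: np.ndarray
    fs_ecg: float
    qrs: object
    cuff_events: pd.DataFrame
    splines: dict = field(default_factory=dict)   # channel -> SmoothedBP


def extract_features(cohort: list, config: PipelineConfig) -> list:
    """Per-beat feature streams for every participant, incl. PCA features.

    The PCA basis is fitted on pooled good-quality beats across the cohort
    (the pipeline's pooling strategy; per-fold refitting is available
    through :func:`ppgbp.ppg_features.fit_pca_basis` directly).
    """
    pc, gc, fc = config.preprocessing, config.gaussian, config.features
    # first pass: segment once to pool beats for the PCA basis
    pooled = []
    segmented = []
    for rec in cohort:
        ppg_f = filter_ppg(rec.ppg, rec.fs_ppg, pc.ppg_band)
        beats = segment_beats(ppg_f, rec.fs_ppg, pc)
        fits = fit_beat_sequence(beats, gc)
        for beat, fit in zip(beats, fits):
            gate_quality(fit, beat, gc.loss_gate)
        segmented.append((rec, beats, fits))
        pooled.extend(beats)
    basis = fit_pca_basis(pooled, pc.sqi_threshold, fc.pca_components,
                          fc.pca_min_beats)

    out = []
    for rec, beats, fits in segmented:
        ecg_f = filter_ecg(rec.ecg, rec.fs_ecg, pc.mains_hz, pc.ecg_highpass)
        qrs = detect_qrs(ecg_f, rec.fs_ecg)
        pats, sqi_pat, pat_beats = compute_pat(qrs, beats, pc.pat_bounds)
        height = rec.demographics.height
        rows = []
        for beat, fit in zip(beats, fits):
            fid = detect_fiducials(beat, fc.apg_search_limit)
            feats = beat_features(beat, fid, fit, height, basis,
                                  fc.nha_harmonics)
            rows.append({"t": beat.onset_time, "sqi": beat.sqi, **feats})
        out.append(ParticipantFeatures(
            participant_id=rec.demographics.participant_id,
            demographics=rec.demographics.as_dict(),
            ppg_stream=pd.DataFrame(rows),
            pat_stream=pd.DataFrame({
                "t": [b.onset_time for b in pat_beats],
                "sqi": sqi_pat, "PAT": pats}),
            ecg_filtered=ecg_f, fs_ecg=rec.fs_ecg, qrs=qrs,
            cuff_events=rec.cuff_events))
    return out


def _ecg_window_rows(pf: ParticipantFeatures, centers: np.ndarray,
                     window_s: float, config: PipelineConfig) -> pd.DataFrame:
    fc = config.features
    sqi_min = config.dataset.sqi_min
    fs = pf.fs_ecg
    half = window_s / 2.0
    n = len(pf.ecg_filtered)
    rows = []
    for tc in centers:
        i0 = max(int((tc - half) * fs), 0)
        i1 = min(int((tc + half) * fs), n)
        # quality: fraction of overlapping SQI blocks that are good
        b0 = int((tc - half) // pf.qrs.block_s)
        b1 = int((tc + half) // pf.qrs.block_s)
        blocks = pf.qrs.sqi_blocks[max(b0, 0):b1 + 1]
        good = np.mean(blocks > sqi_min) if len(blocks) else 0.0
        if good < 0.5 or i1 - i0 < fc.ecg_window_min_s * fs:
            rows.append({"t": tc, **{k: np.nan
                                     for k in ecg_features.ECG_FEATURES}})
            continue
        feats = ecg_features.window_features(
            pf.ecg_filtered[i0:i1], fs, decimate=fc.ecg_decimate,
            m=fc.sampen_m, r_frac=fc.sampen_r, k_max=fc.higuchi_kmax,
            n_bins=fc.shannon_bins, scales=fc.mse_scales)
        rows.append({"t": tc, **feats})
    return pd.DataFrame(rows)


def build_dataset(features: list, config: PipelineConfig,
                  channel: str | None = None):
    """Assemble the calibrated regression dataset for one BP channel.

    Returns ``(CalibratedDataset, CollinearityReport)``.
    """
    channel = channel or config.channel
    dc, rc = config.dataset, config.reference
    rest_end = config.generator.rest_duration
    grid = bp_reference.default_p_grid(rc.p_grid_lo, rc.p_grid_hi,
                                      rc.p_grid_size)
    # cohort-common penalty per channel
    p_by_channel = {}
    for ch in ("sbp", "map", "dbp"):
        cohort_series = [
            bp_reference.CuffSeries(pf.cuff_events["t"].to_numpy(),
                                    pf.cuff_events[ch].to_numpy())
            for pf in features]
        p_by_channel[ch] = bp_reference.select_p(cohort_series, grid)

    frames = []
    baselines_all = {}
    dynamic_cols = None
    for pf in features:
        splines = bp_reference.smooth_recording(pf.cuff_events, p_by_channel)
        pf.splines = splines
        t0 = pf.cuff_events["t"].iloc[0]
        t1 = pf.cuff_events["t"].iloc[-1]
        orig = bp_reference.resample(splines[channel], rc.resample_hz,
                                     (t0, t1))[:, 0]
        t_aug = ds.augmentation_times(t0, t1, dc.augment_hz, orig,
                                      dc.augment_window_s)

        def _window(centers, w):
            parts = [ds.window_features(pf.ppg_stream, centers, w,
                                        dc.sqi_min)]
            if len(pf.pat_stream):
                parts.append(ds.window_features(pf.pat_stream, centers, w,
                                                dc.sqi_min).drop(columns="t"))
            parts.append(_ecg_window_rows(pf, centers, w,
                                          config).drop(columns="t"))
            return pd.concat(parts, axis=1)

        rows_o = _window(orig, dc.window_s)
        rows_o["augmented"] = False
        rows_a = _window(t_aug, dc.augment_window_s)
        rows_a["augmented"] = True
        rows = pd.concat([rows_o, rows_a], ignore_index=True)
        rows = rows.sort_values("t").reset_index(drop=True)

        feat_cols = [c for c in rows.columns if c not in ("t", "augmented")]
        rows = ds.condition_feature_streams(rows, feat_cols, dc.outlier_mad,
                                            dc.outlier_window)
        feat_cols = [c for c in rows.columns if c not in ("t", "augmented")]

        rest = (0.0, rest_end)
        t_rows = rows["t"].to_numpy()
        if not ((t_rows >= rest[0]) & (t_rows <= rest[1])).any():
            # no rest-period rows: one-minute window on the first inflation
            rest = (t0 - 30.0, t0 + 30.0)
            logger.warning("%s: no rest-period rows, calibrating on a "
                           "1-minute window around the first inflation",
                           pf.participant_id)
        calibrated, baselines = ds.calibrate(rows, rest, feat_cols)
        baselines_all[pf.participant_id] = baselines

        # targets and BP calibration values per channel
        for ch in ("sbp", "map", "dbp"):
            ref = splines[ch](calibrated["t"].to_numpy())
            in_rest = ((calibrated["t"] >= rest[0])
                       & (calibrated["t"] <= rest[1]))
            bphat = float(np.mean(splines[ch](
                calibrated.loc[in_rest, "t"].to_numpy())))
            calibrated[f"d{ch}"] = ref - bphat
            if ch == channel:
                calibrated["bp_calibration"] = bphat
        for key in ("age", "sex", "height", "weight", "bmi"):
            calibrated[key] = pf.demographics[key]
        calibrated["participant_id"] = pf.participant_id
        frames.append(calibrated)
        cols = [c for c in calibrated.columns
                if c in set(ALL_PPG_FEATURES)
                | set(ecg_features.ECG_FEATURES) | {"PAT"}]
        dynamic_cols = (cols if dynamic_cols is None
                        else [c for c in dynamic_cols if c in cols])

    table = pd.concat(frames, ignore_index=True)
    table = table.dropna(subset=dynamic_cols).reset_index(drop=True)
    ycols = ["dsbp", "dmap", "ddbp"]
    X = table[["t"] + dynamic_cols + ds.DEMOGRAPHIC_FEATURES]
    dataset = ds.CalibratedDataset(
        X=X, y=table[ycols],
        participant_ids=table["participant_id"].to_numpy(),
        augmented_mask=table["augmented"].to_numpy(dtype=bool),
        dynamic_features=list(dynamic_cols),
        baselines=baselines_all)
    X_red, report = ds.remove_collinear(
        dataset.X.drop(columns="t"), dynamic_cols, dc.vif_threshold)
    X_red.insert(0, "t", dataset.X["t"].to_numpy())
    dataset.X = X_red
    dataset.dynamic_features = [c for c in dynamic_cols
                                if c in X_red.columns]
    return dataset, report


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages; returns a dict of key artifacts."""
    os.makedirs(out_dir, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {"config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": config.seed, "stages": {}}

    logger.info("stage generate: %d participants", config.n_participants)
    cohort = generate_cohort(config.n_participants, config.seed,
                             config.generator)
    write_cohort(cohort, os.path.join(out_dir, "cohort"))
    manifest["stages"]["generate"] = {"participants": len(cohort)}

    logger.info("stage features")
    features = extract_features(cohort, config)
    for pf in features:
        pf.ppg_stream.to_csv(os.path.join(
            out_dir, "cohort", pf.participant_id, "beat_features.csv"),
            index=False)
    manifest["stages"]["features"] = {
        "beats": int(sum(len(pf.ppg_stream) for pf in features))}

    logger.info("stage dataset: channel %s", config.channel)
    dataset, report = build_dataset(features, config, config.channel)
    flat = dataset.X.copy()
    for c in dataset.y.columns:
        flat[c] = dataset.y[c].to_numpy()
    flat["participant_id"] = dataset.participant_ids
    flat["augmented"] = dataset.augmented_mask
    flat.to_csv(os.path.join(out_dir, "dataset.csv"), index=False)
    with open(os.path.join(out_dir, "collinearity.json"), "w") as fh:
        json.dump({"removed": report.removed,
                   "condition_before": report.condition_before,
                   "condition_after": report.condition_after}, fh, indent=1)
    manifest["stages"]["dataset"] = {
        "rows": len(flat), "features_removed": len(report.removed),
        "features_kept": len(dataset.dynamic_features)}

    logger.info("stage estimate: %s on %s", config.model_kind,
                config.feature_set)
    model = estimation.DeltaBPModel(
        dataset, model_kind=config.model_kind, channel=config.channel,
        feature_set=config.feature_set,
        n_trees=config.estimation.n_trees,
        lambda_grid_size=config.estimation.lambda_grid_size,
        hyper_grid=(list(config.estimation.mtry_grid)
                    if config.estimation.mtry_grid else None))
    results = model.fit(seed=config.seed)
    results.metrics_frame().to_csv(os.path.join(out_dir, "metrics.csv"),
                                   index=False)
    results.predictions_frame().to_csv(
        os.path.join(out_dir, "predictions.csv"), index=False)
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
    manifest["stages"]["estimate"] = {"folds": len(results.folds)}

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"cohort": cohort, "features": features, "dataset": dataset,
            "collinearity": report, "results": results,
            "manifest": manifest}
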