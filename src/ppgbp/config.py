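"""Configuration objects for the full ΔBP estimation pipeline.

Every stage of the pipeline is driven by a small frozen-by-convention
dataclass.  Defaults encode the study conditions the pipeline emulates:
a 5-min rest / 10-min phenylephrine dose ramp / 6-min maximum infusion /
8-min washout protocol with one cuff inflation per minute, a cohort
median peak rise in systolic pressure of 20 mmHg, and the processing
constants used throughout (0.5-10 Hz PPG band, SQI threshold 0.8,
Gaussian-fit gate 0.03, 40-s feature windows, VIF threshold 10).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration field holds an invalid value."""


def _require(cond: bool, name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"invalid configuration field '{name}': {message}")


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    Stage durations follow the infusion protocol; BP response magnitudes
    follow the cohort statistics the analysis assumes (median peak rise in
    SBP of 20 mmHg, IQR 8 mmHg, with a minority of strong responders
    exceeding 30 mmHg).
    """

    # protocol (seconds)
    rest_duration: float = 300.0
    ramp_duration: float = 600.0
    max_infusion_duration: float = 360.0
    washout_duration: float = 480.0
    infusion_step: float = 0.2          # mcg/kg/min per minute, 10 increments

    # sampling
    fs_ppg: float = 125.0
    fs_ecg: float = 256.0

    # cuff behaviour
    cuff_interval: float = 60.0         # seconds between scheduled inflations
    cuff_dropout: float = 0.1           # Bernoulli miss probability per inflation
    cuff_noise_sd: float = 4.0          # mmHg, within the +-5 bias / 8 SD device spec

    # hemodynamic response
    median_peak_dsbp: float = 20.0      # mmHg, cohort median of peak rise
    peak_dsbp_iqr: float = 8.0          # mmHg inter-participant IQR
    outlier_fraction: float = 4.0 / 26.0  # strong responders (> 30 mmHg peak)
    outlier_peak_range: tuple = (33.0, 40.0)
    map_peak_ratio: float = 0.85        # peak dMAP / peak dSBP
    dbp_peak_ratio: float = 0.775       # peak dDBP / peak dSBP
    response_lag: float = 60.0          # s, first-order lag of BP behind dose
    washout_tau: float = 150.0          # s, washout decay constant
    baseline_sbp_mean: float = 120.0
    baseline_sbp_sd: float = 8.0
    baseline_dbp_mean: float = 72.0
    baseline_dbp_sd: float = 6.0
    latent_noise_sd: float = 1.0        # mmHg slow physiological fluctuation

    # reflex bradycardia: hr = hr0 - gain * dSBP
    hr_baseline_mean: float = 68.0
    hr_baseline_sd: float = 6.0
    bradycardia_gain: float = 0.3       # bpm per mmHg

    # morphology / signals
    stiffness_ref_dsbp: float = 40.0    # mmHg rise mapping to stiffness = 1
    pat_delay: float = 0.25             # s, R peak -> pulse foot conduction delay
    ppg_noise_sd: float = 0.01          # fraction of unit pulse amplitude
    ppg_resp_mod: float = 0.08          # respiratory amplitude modulation depth
    artifact_rate: float = 0.15         # motion bursts per minute
    artifact_duration: tuple = (1.5, 4.0)   # s
    artifact_amp: float = 1.5
    ecg_noise_sd: float = 0.01
    ecg_wander_amp: float = 0.05
    ecg_wander_hz: float = 0.25
    ecg_mains_amp: float = 0.0          # off by default; tests switch it on
    ecg_mains_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "ramp_duration", "max_infusion_duration",
                     "washout_duration", "cuff_interval"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.fs_ppg >= 50, "fs_ppg", "must be >= 50 Hz")
        _require(self.fs_ecg >= 100, "fs_ecg", "must be >= 100 Hz")
        _require(0 <= self.cuff_dropout < 1, "cuff_dropout", "must be in [0, 1)")
        _require(self.cuff_noise_sd >= 0, "cuff_noise_sd", "must be >= 0")
        _require(0 <= self.outlier_fraction <= 1, "outlier_fraction",
                 "must be in [0, 1]")
        _require(self.median_peak_dsbp > 0, "median_peak_dsbp", "must be positive")
        _require(self.stiffness_ref_dsbp > 0, "stiffness_ref_dsbp",
                 "must be positive")

    @property
    def total_duration(self) -> float:
        return (self.rest_duration + self.ramp_duration
                + self.max_infusion_duration + self.washout_duration)

    def stage_boundaries(self) -> tuple:
        """(end of rest, end of ramp, end of max infusion) in seconds."""
        t1 = self.rest_duration
        t2 = t1 + self.ramp_duration
        t3 = t2 + self.max_infusion_duration
        return (t1, t2, t3)


@dataclass
class PreprocessingConfig:
    ppg_band: tuple = (0.5, 10.0)       # Hz band-pass for the PPG
    ecg_highpass: float = 0.5           # Hz
    mains_hz: float = 50.0
    beat_length: int = 100              # samples per normalised beat
    savgol_window: int = 11
    savgol_order: int = 7
    sqi_threshold: float = 0.8
    sqi_template_beats: int = 20
    pat_bounds: tuple = (0.05, 0.8)     # plausible PAT range, seconds

    def __post_init__(self) -> None:
        _require(self.ppg_band[0] < self.ppg_band[1], "ppg_band",
                 "low cut-off must be below high cut-off")
        _require(self.beat_length >= 50, "beat_length", "must be >= 50")
        _require(self.savgol_window > self.savgol_order, "savgol_window",
                 "must exceed savgol_order")


@dataclass
class GaussianConfig:
    loss_gate: float = 0.03             # fit-RMSE above which SQI is zeroed
    max_nfev: int = 400
    ftol: float = 1e-8
    sigma_floor: float = 1e-4


@dataclass
class FeatureConfig:
    nha_harmonics: int = 10
    apg_search_limit: float = 0.1       # fraction of beat beyond the notch for e
    pca_components: int = 3
    pca_min_beats: int = 10
    ecg_window_min_s: float = 2.0
    ecg_decimate: int = 4               # decimation before entropy features
    sampen_m: int = 2
    sampen_r: float = 0.2               # fraction of window SD
    mse_scales: tuple = (2, 4, 6, 8)
    higuchi_kmax: int = 17
    shannon_bins: int = 16


@dataclass
class ReferenceConfig:
    p_grid_lo: float = 1e-3
    p_grid_hi: float = 1e8
    p_grid_size: int = 12               # one point per decade by default
    resample_hz: float = 1.0 / 60.0


@dataclass
class DatasetConfig:
    window_s: float = 40.0
    augment_window_s: float = 15.0
    augment_hz: float = 1.0 / 15.0
    sqi_min: float = 0.8
    outlier_mad: float = 5.0
    outlier_window: int = 10
    vif_threshold: float = 10.0


@dataclass
class EstimationConfig:
    n_trees: int = 300
    mtry_grid: tuple = ()               # empty -> derived from M
    lambda_grid_size: int = 30
    lambda_min_ratio: float = 1e-4


@dataclass
class ImportanceConfig:
    background_size: int = 100
    kernel_nsamples: int = 2048
    max_explain_rows: int = 200


@dataclass
class PipelineConfig:
    """Aggregate configuration; round-trips losslessly through YAML."""

    n_participants: int = 26
    seed: int = 0
    channel: str = "sbp"
    model_kind: str = "rf"
    feature_set: str = "ppg"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    gaussian: GaussianConfig = field(default_factory=GaussianConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)

    def __post_init__(self) -> None:
        _require(self.n_participants >= 1, "n_participants", "must be >= 1")
        _require(self.channel in ("sbp", "map", "dbp"), "channel",
                 "must be one of sbp/map/dbp")
        _require(self.model_kind in ("lasso_ols", "rf"), "model_kind",
                 "must be lasso_ols or rf")
        _require(self.feature_set in ("ppg", "ecg", "ppg+ecg", "pat"),
                 "feature_set", "must be one of ppg/ecg/ppg+ecg/pat")

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        sub = {f.name: f.type for f in dataclasses.fields(cls)}
        subclasses = {
            "generator": GeneratorConfig,
            "preprocessing": PreprocessingConfig,
            "gaussian": GaussianConfig,
            "features": FeatureConfig,
            "reference": ReferenceConfig,
            "dataset": DatasetConfig,
            "estimation": EstimationConfig,
            "importance": ImportanceConfig,
        }
        for key, value in data.items():
            if key not in sub:
                raise ConfigurationError(f"unknown configuration key '{key}'")
            if key in subclasses:
                known = {f.name for f in dataclasses.fields(subclasses[key])}
                bad = set(value) - known
                if bad:
                    raise ConfigurationError(
                        f"unknown configuration key '{key}.{sorted(bad)[0]}'")
                value = {k: (tuple(v) if isinstance(v, list) else v)
                         for k, v in value.items()}
                kwargs[key] = subclasses[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
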