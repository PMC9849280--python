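"""Synthetic cohort generator.

Produces per-participant PPG, single-lead ECG and sparse cuff blood-pressure
recordings with the statistical structure of a phenylephrine pressor study:
a rest / dose-ramp / maximum-infusion / washout protocol, a configurable
cohort distribution of peak systolic rises (median 20 mmHg, IQR 8 mmHg,
a minority of responders above 30 mmHg), reflex bradycardia, and a
stiffness-driven change in pulse morphology (growing tidal wave, diminishing
dicrotic notch).

Each PPG beat is the sum of four Gaussians in normalised beat time; the
ground-truth parameters, beat onsets, R-peak times and artefact masks are
emitted alongside the signals so downstream detectors and fitters can be
tested against a known truth.  The generator is deliberately statistical,
not biophysical: no Windkessel or pharmacokinetic modelling is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GeneratorConfig

__all__ = [
    "Demographics", "LatentHemodynamics", "Recording", "GroundTruth",
    "generate_cohort", "generate_recording", "synthesize_ppg",
    "synthesize_ecg", "beat_parameters", "write_cohort", "read_cohort",
    "THETA_REST", "THETA_STIFF",
]

# Hand-tuned rest and maximum-stiffness 4-Gaussian parameter sets.  The rest
# set shows a dominant systolic wave, a modest tidal wave, a clear dicrotic
# notch and diastolic peak; the stiff set raises and advances the tidal wave
# (g2) until it overshadows the systolic peak and fills in the notch.
# Columns: amplitude, mean (normalised time), width.
THETA_REST = np.array([
    [0.80, 0.23, 0.080],
    [0.42, 0.46, 0.110],
    [0.28, 0.67, 0.075],
    [0.12, 0.85, 0.080],
])
THETA_STIFF = np.array([
    [0.84, 0.22, 0.082],
    [0.95, 0.40, 0.125],
    [0.38, 0.58, 0.090],
    [0.16, 0.80, 0.085],
])


@dataclass
class Demographics:
    participant_id: str
    age: float          # years
    sex: int            # 0 = male, 1 = female
    height: float       # cm
    weight: float       # kg

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2

    def as_dict(self) -> dict:
        return {"participant_id": self.participant_id, "age": self.age,
                "sex": self.sex, "height": self.height, "weight": self.weight,
                "bmi": self.bmi}


@dataclass
class LatentHemodynamics:
    """1-Hz latent time series driving the signal synthesis."""

    t: np.ndarray
    sbp: np.ndarray
    map: np.ndarray
    dbp: np.ndarray
    hr: np.ndarray
    stiffness: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "sbp": self.sbp, "map": self.map,
                             "dbp": self.dbp, "hr": self.hr,
                             "stiffness": self.stiffness})


@dataclass
class GroundTruth:
    beat_onsets: np.ndarray          # s, PPG pulse feet
    r_times: np.ndarray              # s, ECG R peaks
    theta: np.ndarray                # (n_beats, 4, 3) Gaussian parameters
    artifact_intervals: list         # [(t0, t1), ...] PPG motion bursts
    pat_delay: float                 # s
    peak_dsbp: float                 # mmHg


@dataclass
class Recording:
    demographics: Demographics
    ppg: np.ndarray
    fs_ppg: float
    ecg: np.ndarray
    fs_ecg: float
    cuff_events: pd.DataFrame        # columns t, sbp, map, dbp (sorted by t)
    latent: LatentHemodynamics
    ground_truth: GroundTruth
    infusion_rate: np.ndarray = field(default=None)  # mcg/kg/min at latent t


# ---------------------------------------------------------------------------
# latent hemodynamics


def _stage_of(t: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    t1, t2, t3 = config.stage_boundaries()
    stage = np.full(t.shape, "washout", dtype=object)
    stage[t < t3] = "max_infusion"
    stage[t < t2] = "dose_increase"
    stage[t < t1] = "rest"
    return stage


def infusion_profile(t: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Infusion rate in mcg/kg/min: 10 stepwise increments during the ramp."""
    t1, t2, t3 = config.stage_boundaries()
    rate = np.zeros_like(t, dtype=float)
    in_ramp = (t >= t1) & (t < t2)
    step_len = config.ramp_duration / 10.0
    increments = np.minimum(np.floor((t[in_ramp] - t1) / step_len) + 1, 10)
    rate[in_ramp] = config.infusion_step * increments
    rate[(t >= t2) & (t < t3)] = config.infusion_step * 10
    return rate


def _response_curve(t: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Normalised BP response in [0, 1]: dose-proportional with lag + washout."""
    t1, t2, t3 = config.stage_boundaries()
    rate = infusion_profile(t, config)
    target = rate / (config.infusion_step * 10)
    target[t >= t3] = 0.0
    # first-order lag, explicit Euler on the latent grid
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    s = np.zeros_like(target)
    for i in range(1, len(t)):
        tau = config.washout_tau if t[i] >= t3 else config.response_lag
        s[i] = s[i - 1] + dt / tau * (target[i] - s[i - 1])
    peak = s.max()
    return s / peak if peak > 0 else s


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  smooth: int = 30) -> np.ndarray:
    """Slow, zero-mean fluctuation produced by moving-averaging white noise."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, sd, n + smooth)
    kernel = np.ones(smooth) / smooth
    out = np.convolve(raw, kernel, mode="same")[:n]
    return (out - out.mean()) * (sd / max(out.std(), 1e-12))


def generate_latent(rng: np.random.Generator, peak_dsbp: float,
                    config: GeneratorConfig) -> LatentHemodynamics:
    t = np.arange(0.0, config.total_duration, 1.0)
    s = _response_curve(t, config)
    sbp0 = rng.normal(config.baseline_sbp_mean, config.baseline_sbp_sd)
    dbp0 = rng.normal(config.baseline_dbp_mean, config.baseline_dbp_sd)
    dbp0 = min(dbp0, sbp0 - 25.0)   # keep a plausible pulse pressure

    dsbp = peak_dsbp * s + _smooth_noise(rng, len(t), config.latent_noise_sd)
    dmap = config.map_peak_ratio * peak_dsbp * s + _smooth_noise(
        rng, len(t), config.latent_noise_sd)
    ddbp = config.dbp_peak_ratio * peak_dsbp * s + _smooth_noise(
        rng, len(t), config.latent_noise_sd)

    sbp = sbp0 + dsbp
    dbp = dbp0 + ddbp
    map0 = dbp0 + (sbp0 - dbp0) / 3.0
    map_ = map0 + dmap
    # enforce sbp > map > dbp at every sample
    map_ = np.clip(map_, dbp + 1.0, sbp - 1.0)

    hr0 = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
    hr = np.maximum(hr0 - config.bradycardia_gain * (sbp - sbp0), 40.0)
    stiffness = np.clip((sbp - sbp0) / config.stiffness_ref_dsbp, 0.0, 1.0)
    return LatentHemodynamics(t=t, sbp=sbp, map=map_, dbp=dbp, hr=hr,
                              stiffness=stiffness)


# ---------------------------------------------------------------------------
# PPG synthesis


def _gauss_sum(tau: np.ndarray, theta: np.ndarray) -> np.ndarray:
    out = np.zeros_like(tau)
    for amp, mu, sig in theta:
        out += amp * np.exp(-((tau - mu) ** 2) / (2.0 * sig ** 2))
    return out


def beat_parameters(stiffness: float) -> np.ndarray:
    """Interpolate the 4-Gaussian parameter set for a stiffness in [0, 1]."""
    s = float(np.clip(stiffness, 0.0, 1.0))
    return (1.0 - s) * THETA_REST + s * THETA_STIFF


def _beat_schedule(latent: LatentHemodynamics, duration: float) -> np.ndarray:
    """Beat onset times from the instantaneous heart rate (period = 60/hr)."""
    onsets = [0.1]
    while True:
        hr = np.interp(onsets[-1], latent.t, latent.hr)
        nxt = onsets[-1] + 60.0 / hr
        if nxt >= duration - 0.2:
            break
        onsets.append(nxt)
    return np.asarray(onsets)


def synthesize_ppg(latent: LatentHemodynamics, fs: float, seed,
                   config: GeneratorConfig | None = None,
                   beat_onsets: np.ndarray | None = None):
    """Render a continuous PPG from the latent series.

    Returns ``(ppg, onsets, theta, artifact_intervals)`` where ``theta`` is
    the per-beat ground-truth Gaussian parameter array.
    """
    config = config or GeneratorConfig()
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz for PPG synthesis")
    if not (np.all(np.isfinite(latent.sbp)) and np.all(np.isfinite(latent.hr))):
        raise ValueError("latent hemodynamic series must be finite")
    rng = np.random.default_rng(seed)
    duration = latent.t[-1] + 1.0
    if beat_onsets is None:
        beat_onsets = _beat_schedule(latent, duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ppg = np.zeros(n)
    thetas = np.empty((len(beat_onsets), 4, 3))
    periods = np.diff(np.append(beat_onsets, duration))
    for k, (onset, period) in enumerate(zip(beat_onsets, periods)):
        stiff = np.interp(onset, latent.t, latent.stiffness)
        theta = beat_parameters(stiff)
        thetas[k] = theta
        i0 = int(np.ceil(onset * fs))
        i1 = min(int(np.ceil((onset + period) * fs)), n)
        tau = (t[i0:i1] - onset) / period
        amp = 1.0 + config.ppg_resp_mod * np.sin(2 * np.pi * 0.25 * onset)
        ppg[i0:i1] = amp * _gauss_sum(tau, theta)

    artifacts = []
    n_bursts = rng.poisson(config.artifact_rate * duration / 60.0)
    for _ in range(n_bursts):
        t0 = rng.uniform(0, duration)
        length = rng.uniform(*config.artifact_duration)
        i0, i1 = int(t0 * fs), min(int((t0 + length) * fs), n)
        if i1 <= i0:
            continue
        burst = rng.normal(0, config.artifact_amp, i1 - i0)
        # low-pass-ish burst to mimic motion rather than white noise
        burst = np.convolve(burst, np.ones(7) / 7.0, mode="same")
        ppg[i0:i1] += burst
        artifacts.append((t0, min(t0 + length, duration)))
    if config.ppg_noise_sd > 0:
        ppg = ppg + rng.normal(0, config.ppg_noise_sd, n)
    return ppg, beat_onsets, thetas, artifacts


# ---------------------------------------------------------------------------
# ECG synthesis

# P-QRS-T template waves in normalised beat phase relative to the R peak:
# (amplitude, phase offset, phase width)
_ECG_WAVES = np.array([
    [0.15, -0.18, 0.025],   # P
    [-0.12, -0.028, 0.010],  # Q
    [1.00, 0.0, 0.009],      # R
    [-0.22, 0.030, 0.012],   # S
    [0.35, 0.30, 0.045],     # T
])


def synthesize_ecg(latent: LatentHemodynamics, fs: float, seed,
                   config: GeneratorConfig | None = None,
                   r_times: np.ndarray | None = None):
    """Render a single-lead ECG; returns ``(ecg, r_times)``."""
    config = config or GeneratorConfig()
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz for ECG synthesis")
    if not np.all(np.isfinite(latent.hr)):
        raise ValueError("latent hemodynamic series must be finite")
    rng = np.random.default_rng(seed)
    duration = latent.t[-1] + 1.0
    if r_times is None:
        r_times = _beat_schedule(latent, duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    periods = np.diff(np.append(r_times, duration + 60.0 / latent.hr[-1]))
    for r, period in zip(r_times, periods):
        i0 = max(int((r - 0.35 * period) * fs), 0)
        i1 = min(int((r + 0.72 * period) * fs), n)
        u = (t[i0:i1] - r) / period
        seg = np.zeros(i1 - i0)
        for amp, mu, sig in _ECG_WAVES:
            seg += amp * np.exp(-((u - mu) ** 2) / (2.0 * sig ** 2))
        ecg[i0:i1] += seg
    if config.ecg_wander_amp > 0:
        ecg += config.ecg_wander_amp * np.sin(
            2 * np.pi * config.ecg_wander_hz * t + rng.uniform(0, 2 * np.pi))
    if config.ecg_mains_amp > 0:
        ecg += config.ecg_mains_amp * np.sin(2 * np.pi * config.ecg_mains_hz * t)
    if config.ecg_noise_sd > 0:
        ecg += rng.normal(0, config.ecg_noise_sd, n)
    return ecg, r_times


# ---------------------------------------------------------------------------
# cohort assembly


def _sample_demographics(rng: np.random.Generator, pid: str) -> Demographics:
    sex = int(rng.uniform() < 0.538)            # 1 = female
    if sex:
        height = rng.normal(165.0, 6.0)
    else:
        height = rng.normal(178.0, 7.0)
    age = float(np.clip(rng.normal(29.0, 7.0), 18.0, 45.0))
    bmi = float(np.clip(rng.normal(22.5, 3.0), 17.5, 32.0))
    weight = bmi * (height / 100.0) ** 2
    return Demographics(participant_id=pid, age=age, sex=sex,
                        height=float(height), weight=float(weight))


def _sample_peak_dsbp(rng: np.random.Generator,
                      config: GeneratorConfig) -> float:
    """Peak rise in SBP; normal body with designated strong responders."""
    if rng.uniform() < config.outlier_fraction:
        return float(rng.uniform(*config.outlier_peak_range))
    sd = config.peak_dsbp_iqr / 1.349   # IQR of a normal = 1.349 sd
    peak = rng.normal(config.median_peak_dsbp, sd)
    return float(np.clip(peak, 5.0, 30.0))


def generate_recording(seed, pid: str,
                       config: GeneratorConfig | None = None) -> Recording:
    """Generate one participant's full recording from an integer seed."""
    config = config or GeneratorConfig()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rngs = [np.random.default_rng(c) for c in ss.spawn(5)]
    demo = _sample_demographics(rngs[0], pid)
    peak = _sample_peak_dsbp(rngs[0], config)
    latent = generate_latent(rngs[1], peak, config)

    duration = latent.t[-1] + 1.0
    r_times = _beat_schedule(latent, duration)
    pulse_onsets = r_times + config.pat_delay

    ppg, onsets, thetas, artifacts = synthesize_ppg(
        latent, config.fs_ppg, rngs[2], config, beat_onsets=pulse_onsets)
    ecg, r_times = synthesize_ecg(
        latent, config.fs_ecg, rngs[3], config, r_times=r_times)

    # cuff events: scheduled every cuff_interval, Bernoulli dropout, noise
    rng_cuff = rngs[4]
    sched = np.arange(config.cuff_interval / 2.0, config.total_duration,
                      config.cuff_interval)
    rows = []
    for tc in sched:
        if rng_cuff.uniform() < config.cuff_dropout:
            continue
        noise = rng_cuff.normal(0.0, config.cuff_noise_sd, 3) \
            if config.cuff_noise_sd > 0 else np.zeros(3)
        rows.append({
            "t": tc,
            "sbp": np.interp(tc, latent.t, latent.sbp) + noise[0],
            "map": np.interp(tc, latent.t, latent.map) + noise[1],
            "dbp": np.interp(tc, latent.t, latent.dbp) + noise[2],
        })
    cuff = pd.DataFrame(rows, columns=["t", "sbp", "map", "dbp"])

    gt = GroundTruth(beat_onsets=onsets, r_times=r_times, theta=thetas,
                     artifact_intervals=artifacts, pat_delay=config.pat_delay,
                     peak_dsbp=peak)
    return Recording(demographics=demo, ppg=ppg, fs_ppg=config.fs_ppg,
                     ecg=ecg, fs_ecg=config.fs_ecg, cuff_events=cuff,
                     latent=latent, ground_truth=gt,
                     infusion_rate=infusion_profile(latent.t, config))


def generate_cohort(n_participants: int, seed,
                    config: GeneratorConfig | None = None) -> list:
    """Generate a deterministic synthetic cohort of ``n_participants``."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    config = config or GeneratorConfig()
    children = np.random.SeedSequence(seed).spawn(n_participants)
    return [generate_recording(child, f"P{i + 1:03d}", config)
            for i, child in enumerate(children)]


# ---------------------------------------------------------------------------
# disk layout: one directory per participant, plain CSV


def write_cohort(recordings: list, out_dir) -> pd.DataFrame:
    """Write a cohort as two-column CSV signals + cuff/demographics CSVs."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for rec in recordings:
        pid = rec.demographics.participant_id
        pdir = os.path.join(out_dir, pid)
        os.makedirs(pdir, exist_ok=True)
        for name, sig, fs in (("ppg", rec.ppg, rec.fs_ppg),
                              ("ecg", rec.ecg, rec.fs_ecg)):
            t = np.arange(len(sig)) / fs
            pd.DataFrame({"t": t, "value": sig}).to_csv(
                os.path.join(pdir, f"{name}.csv"), index=False)
        rec.cuff_events.to_csv(os.path.join(pdir, "cuff.csv"), index=False)
        pd.DataFrame([rec.demographics.as_dict()]).to_csv(
            os.path.join(pdir, "demographics.csv"), index=False)
        rec.latent.frame().to_csv(os.path.join(pdir, "latent.csv"), index=False)
        manifest.append({"participant_id": pid, "path": pid,
                         "fs_ppg": rec.fs_ppg, "fs_ecg": rec.fs_ecg})
    mf = pd.DataFrame(manifest)
    mf.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return mf


def read_cohort(out_dir) -> list:
    """Read back the signal/cuff/demographics layout (no ground truth)."""
    import os

    mf = pd.read_csv(os.path.join(out_dir, "manifest.csv"))
    recordings = []
    for _, row in mf.iterrows():
        pdir = os.path.join(out_dir, row["path"])
        ppg = pd.read_csv(os.path.join(pdir, "ppg.csv"))["value"].to_numpy()
        ecg = pd.read_csv(os.path.join(pdir, "ecg.csv"))["value"].to_numpy()
        cuff = pd.read_csv(os.path.join(pdir, "cuff.csv"))
        demo_row = pd.read_csv(os.path.join(pdir, "demographics.csv")).iloc[0]
        demo = Demographics(participant_id=str(demo_row["participant_id"]),
                            age=float(demo_row["age"]), sex=int(demo_row["sex"]),
                            height=float(demo_row["height"]),
                            weight=float(demo_row["weight"]))
        lat = pd.read_csv(os.path.join(pdir, "latent.csv"))
        latent = LatentHemodynamics(
            t=lat["t"].to_numpy(), sbp=lat["sbp"].to_numpy(),
            map=lat["map"].to_numpy(), dbp=lat["dbp"].to_numpy(),
            hr=lat["hr"].to_numpy(), stiffness=lat["stiffness"].to_numpy())
        recordings.append(Recording(
            demographics=demo, ppg=ppg, fs_ppg=float(row["fs_ppg"]),
            ecg=ecg, fs_ecg=float(row["fs_ecg"]), cuff_events=cuff,
            latent=latent, ground_truth=None))
    return recordings
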