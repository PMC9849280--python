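"""Shared fixtures: small, deterministic synthetic recordings."""

import numpy as np
import pytest

from ppgbp.config import GeneratorConfig, PreprocessingConfig
from ppgbp.gaussian import evaluate
from ppgbp.preprocessing import NormalizedBeat
from ppgbp.synthetic import beat_parameters, generate_recording
from scipy.signal import savgol_filter


def quiet_config(**kwargs) -> GeneratorConfig:
    """Short, noise-free protocol for oracle tests."""
    defaults = dict(rest_duration=60.0, ramp_duration=120.0,
                    max_infusion_duration=60.0, washout_duration=60.0,
                    cuff_interval=20.0, ppg_noise_sd=0.0, artifact_rate=0.0,
                    latent_noise_sd=0.0, ecg_noise_sd=0.0, ecg_wander_amp=0.0,
                    ppg_resp_mod=0.0, cuff_noise_sd=0.0, cuff_dropout=0.0)
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def clean_recording():
    return generate_recording(11, "P001", quiet_config())


@pytest.fixture(scope="session")
def noisy_recording():
    cfg = quiet_config(ppg_noise_sd=0.01, ecg_noise_sd=0.01,
                       ecg_wander_amp=0.05, latent_noise_sd=1.0,
                       cuff_noise_sd=4.0, cuff_dropout=0.1,
                       artifact_rate=0.3, ppg_resp_mod=0.08)
    return generate_recording(12, "P002", cfg)


def model_beat(stiffness: float = 0.0, n: int = 100) -> NormalizedBeat:
    """A beat that IS the 4-Gaussian model (no renormalisation)."""
    theta = beat_parameters(stiffness)
    grid = np.linspace(0.0, 1.0, n)
    zeta = evaluate(theta, grid)
    delta = grid[1]
    return NormalizedBeat(
        zeta=zeta,
        vpg=savgol_filter(zeta, 11, 7, deriv=1, delta=delta),
        apg=savgol_filter(zeta, 11, 7, deriv=2, delta=delta),
        onset_time=0.0, duration=1.0)


def normalized_model_beat(stiffness: float = 0.0, n: int = 100,
                          config: PreprocessingConfig | None = None):
    """Model beat passed through the real normalisation path."""
    from ppgbp.preprocessing import normalize_beat

    theta = beat_parameters(stiffness)
    grid = np.linspace(0.0, 1.0, n)
    seg = evaluate(theta, grid)
    return normalize_beat(seg, fs=float(n), onset_time=0.0,
                          config=config or PreprocessingConfig())
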