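"""Signal conditioning: filtering, beat segmentation, QRS detection, PAT.

The PPG is band-pass filtered (0.5-10 Hz Butterworth, zero phase), segmented
into onset-to-onset beats, and each beat is resampled to a fixed length and
min-max normalised to unit amplitude and unit duration.  First and second
derivatives (velocity and acceleration plethysmogram, VPG/APG) come from
Savitzky-Golay differentiation.  The ECG is high-pass filtered with a mains
notch and QRS complexes are found with a Pan-Tompkins detector; a second,
independent detector provides a block-wise agreement signal-quality index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .config import PreprocessingConfig

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedBeat", "QrsAnnotation", "filter_ppg", "filter_ecg",
    "segment_beats", "detect_qrs", "compute_pat", "normalize_beat",
]


@dataclass
class NormalizedBeat:
    """One PPG pulse rescaled to unit amplitude and unit duration."""

    zeta: np.ndarray          # normalised pulse, min 0 / max 1
    vpg: np.ndarray           # d(zeta)/dt on the unit interval
    apg: np.ndarray           # d2(zeta)/dt2
    onset_time: float         # seconds in the original recording
    duration: float           # seconds
    sqi: float = 1.0

    @property
    def t(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, len(self.zeta))


@dataclass
class QrsAnnotation:
    r_peak_times: np.ndarray               # seconds, strictly increasing
    sqi_blocks: np.ndarray = field(default=None)   # (block_start, sqi) rows
    block_s: float = 10.0

    def sqi_at(self, t: float) -> float:
        if self.sqi_blocks is None or len(self.sqi_blocks) == 0:
            return 0.0
        idx = int(np.clip(t // self.block_s, 0, len(self.sqi_blocks) - 1))
        return float(self.sqi_blocks[idx])


# ---------------------------------------------------------------------------
# filters


def filter_ppg(raw: np.ndarray, fs: float,
               band: tuple = (0.5, 10.0)) -> np.ndarray:
    """Zero-phase 8th-order Butterworth band-pass (default 0.5-10 Hz)."""
    if fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {band[1]} Hz cut-off")
    # butter order 4 band-pass -> 8th-order transfer function
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))


def filter_ecg(raw: np.ndarray, fs: float, mains_hz: float = 50.0,
               highpass: float = 0.5) -> np.ndarray:
    """8th-order Butterworth high-pass then 2nd-order mains notch, zero phase."""
    if fs <= 2 * mains_hz:
        raise ValueError(
            f"sampling rate {fs} Hz too low to notch {mains_hz} Hz")
    sos = signal.butter(8, highpass, btype="highpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(raw, dtype=float))
    b, a = signal.iirnotch(mains_hz, Q=30.0, fs=fs)
    return signal.filtfilt(b, a, out)


# ---------------------------------------------------------------------------
# beat segmentation


def normalize_beat(segment: np.ndarray, fs: float, onset_time: float,
                   config: PreprocessingConfig | None = None) -> NormalizedBeat:
    """Resample one onset-to-onset segment and normalise to [0, 1] x [0, 1]."""
    config = config or PreprocessingConfig()
    L = config.beat_length
    x = np.linspace(0.0, 1.0, len(segment))
    xi = np.linspace(0.0, 1.0, L)
    zeta = interpolate.CubicSpline(x, segment)(xi)
    rng_amp = zeta.max() - zeta.min()
    if rng_amp <= 0:
        zeta = np.zeros(L)
    else:
        zeta = (zeta - zeta.min()) / rng_amp
    delta = 1.0 / (L - 1)
    vpg = signal.savgol_filter(zeta, config.savgol_window, config.savgol_order,
                               deriv=1, delta=delta)
    apg = signal.savgol_filter(zeta, config.savgol_window, config.savgol_order,
                               deriv=2, delta=delta)
    return NormalizedBeat(zeta=zeta, vpg=vpg, apg=apg, onset_time=onset_time,
                          duration=len(segment) / fs)


def _detect_onsets(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Pulse feet via maximum-upslope detection followed by local minima."""
    d = np.gradient(ppg) * fs
    pos = d[d > 0]
    if len(pos) == 0:
        return np.array([], dtype=int)
    height = 0.45 * np.percentile(pos, 90)
    upslopes, _ = signal.find_peaks(d, height=height, distance=int(0.4 * fs))
    onsets = []
    back = int(0.3 * fs)
    for p in upslopes:
        lo = max(p - back, 0)
        onsets.append(lo + int(np.argmin(ppg[lo:p + 1])))
    onsets = np.unique(onsets)
    return onsets


def segment_beats(ppg: np.ndarray, fs: float,
                  config: PreprocessingConfig | None = None) -> list:
    """Segment a (filtered) PPG into normalised beats with per-beat SQI.

    The SQI is the Pearson correlation of each normalised beat against a
    running template (mean of up to the last ``sqi_template_beats`` accepted
    beats), clipped to [0, 1].
    """
    config = config or PreprocessingConfig()
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 5 * fs:
        raise ValueError("need at least 5 s of signal to segment beats")
    onsets = _detect_onsets(ppg, fs)
    if len(onsets) < 2:
        logger.warning("no detectable pulses in PPG segment")
        return []
    beats = []
    accepted: list = []
    for i0, i1 in zip(onsets[:-1], onsets[1:]):
        dur = (i1 - i0) / fs
        if not (0.3 <= dur <= 2.0):
            continue
        beat = normalize_beat(ppg[i0:i1 + 1], fs, i0 / fs, config)
        if accepted:
            template = np.mean(accepted[-config.sqi_template_beats:], axis=0)
            denom = np.std(beat.zeta) * np.std(template)
            if denom <= 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(beat.zeta, template)[0, 1])
            beat.sqi = float(np.clip(corr, 0.0, 1.0))
        else:
            beat.sqi = 1.0
        if beat.sqi > config.sqi_threshold:
            accepted.append(beat.zeta)
        beats.append(beat)
    return beats


# ---------------------------------------------------------------------------
# QRS detection (Pan-Tompkins) and ECG quality


def _pan_tompkins(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Classic Pan-Tompkins stages; returns R-peak sample indices."""
    sos = signal.butter(3, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp) * fs
    squared = deriv ** 2
    win = max(int(0.150 * fs), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    peaks, _ = signal.find_peaks(mwi, distance=int(0.25 * fs))
    if len(peaks) == 0:
        return np.array([], dtype=int)
    # adaptive signal/noise thresholds
    spki = float(np.percentile(mwi[peaks], 75)) / 2.0
    npki = float(np.percentile(mwi[peaks], 25)) / 2.0
    threshold = npki + 0.25 * (spki - npki)
    r_idx = []
    for p in peaks:
        if mwi[p] > threshold:
            spki = 0.125 * mwi[p] + 0.875 * spki
            r_idx.append(p)
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)
    # refine to the band-passed ECG maximum near each integration peak
    half = int(0.08 * fs)
    refined = []
    for p in r_idx:
        lo, hi = max(p - half, 0), min(p + half + 1, len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory period of 250 ms
    keep = []
    for idx in refined:
        if keep and (idx - keep[-1]) < int(0.25 * fs):
            if bp[idx] > bp[keep[-1]]:
                keep[-1] = idx
        else:
            keep.append(idx)
    return np.asarray(keep, dtype=int)


def _amplitude_detector(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Independent detector: thresholded peaks of the band-passed signal."""
    sos = signal.butter(2, (8.0, 20.0), btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    height = 0.5 * np.percentile(np.abs(bp), 99.5)
    peaks, _ = signal.find_peaks(np.abs(bp), height=height,
                                 distance=int(0.25 * fs))
    return peaks


def detect_qrs(ecg: np.ndarray, fs: float, block_s: float = 10.0,
               match_tol: float = 0.05) -> QrsAnnotation:
    """Detect QRS complexes and score ECG quality per analysis block.

    Quality per block is the agreement fraction between the Pan-Tompkins
    detector and an independent amplitude detector within ±50 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 5 * fs:
        raise ValueError("need at least 5 s of signal for QRS detection")
    if np.ptp(ecg) <= 1e-12:
        n_blocks = max(int(np.ceil(len(ecg) / fs / block_s)), 1)
        return QrsAnnotation(r_peak_times=np.array([]),
                             sqi_blocks=np.zeros(n_blocks), block_s=block_s)
    idx1 = _pan_tompkins(ecg, fs)
    idx2 = _amplitude_detector(ecg, fs)
    t1, t2 = idx1 / fs, idx2 / fs

    duration = len(ecg) / fs
    n_blocks = max(int(np.ceil(duration / block_s)), 1)
    sqi = np.zeros(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block_s, (b + 1) * block_s
        in1 = t1[(t1 >= lo) & (t1 < hi)]
        in2 = t2[(t2 >= lo) & (t2 < hi)]
        if len(in1) == 0 and len(in2) == 0:
            sqi[b] = 0.0
            continue
        matched = 0
        used = np.zeros(len(in2), dtype=bool)
        for t in in1:
            if len(in2) == 0:
                break
            j = int(np.argmin(np.abs(in2 - t)))
            if not used[j] and abs(in2[j] - t) <= match_tol:
                used[j] = True
                matched += 1
        denom = max(len(in1), len(in2))
        agreement = matched / denom if denom else 0.0
        # physiological plausibility: R-R intervals close to the block median
        rr = np.diff(in1)
        if len(rr) >= 2:
            med = np.median(rr)
            regular = float(np.mean((np.abs(rr - med) <= 0.15 * med)
                                    & (rr >= 0.3) & (rr <= 2.0)))
        else:
            regular = 0.0
        sqi[b] = agreement * regular
    return QrsAnnotation(r_peak_times=t1, sqi_blocks=sqi, block_s=block_s)


# ---------------------------------------------------------------------------
# pulse arrival time


def compute_pat(qrs: QrsAnnotation, beats: list,
                bounds: tuple = (0.05, 0.8)):
    """Per-beat pulse arrival time (pulse onset minus preceding R peak).

    Returns ``(pat_seconds, sqi_pat, beats_used)``; beats with no preceding
    R peak are skipped, values outside ``bounds`` keep their value but are
    flagged with ``sqi_pat = 0``.
    """
    r = np.asarray(qrs.r_peak_times)
    pats, sqis, used = [], [], []
    for beat in beats:
        earlier = r[r <= beat.onset_time]
        if len(earlier) == 0:
            continue
        pat = beat.onset_time - earlier[-1]
        pats.append(pat)
        sqis.append(0.0 if not (bounds[0] <= pat <= bounds[1]) else beat.sqi)
        used.append(beat)
    return np.asarray(pats), np.asarray(sqis), used
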