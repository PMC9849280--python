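"""Fiducial-point detection on normalised PPG beats.

Landmarks: max-slope point W, systolic peak S (first turning point above the
pulse midpoint -- robust to a tidal wave growing taller than the true
systolic peak under vasoconstriction), dicrotic notch N, diastolic peak D,
and the a-e extrema of the acceleration plethysmogram.  When arterial
stiffening erases the notch, N is inferred from the APG and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocessing import NormalizedBeat

__all__ = ["FiducialSet", "detect_systolic_peak", "detect_notch_diastolic",
           "detect_apg_waves", "detect_fiducials"]

_PROMINENCE = 0.01      # 'turning point' = local max with this prominence
_NOTCH_WINDOW = 0.5     # beat-fraction after S searched for the notch


@dataclass
class FiducialSet:
    t_W: float = np.nan
    t_S: float = np.nan
    t_N: float = np.nan
    t_D: float = np.nan
    amp_S: float = np.nan
    amp_N: float = np.nan
    amp_D: float = np.nan
    apg_times: dict = field(default_factory=dict)    # 'a'..'e' -> time
    apg_amps: dict = field(default_factory=dict)     # 'a'..'e' -> APG value
    valid: dict = field(default_factory=dict)        # point -> bool
    notch_inferred: bool = False
    systolic_fallback: bool = False

    def is_valid(self, point: str) -> bool:
        return bool(self.valid.get(point, False))


def _local_maxima(x: np.ndarray, prominence: float = _PROMINENCE):
    peaks, _ = signal.find_peaks(x, prominence=prominence)
    return peaks


def detect_systolic_peak(beat: NormalizedBeat):
    """First local maximum above the pulse midpoint.

    Falls back to the global maximum when no such turning point exists
    (flagged); a monotone beat yields an invalid result.
    """
    zeta = beat.zeta
    t = beat.t
    peaks = _local_maxima(zeta)
    above = [p for p in peaks if zeta[p] > 0.5]
    if above:
        p = above[0]
        return float(t[p]), float(zeta[p]), True, False
    g = int(np.argmax(zeta))
    if g == 0 or g == len(zeta) - 1:
        return np.nan, np.nan, False, False       # monotone beat
    return float(t[g]), float(zeta[g]), True, True


def detect_notch_diastolic(beat: NormalizedBeat, t_S: float):
    """Dicrotic notch and diastolic peak after the systolic peak.

    The notch is the first local minimum of the pulse (positive-going VPG
    zero crossing) in (t_S, t_S + 0.5]; when the notch has been lost the
    fallback is the most prominent APG local maximum in the window (flagged
    inferred).  D is the first local maximum after N, degrading to N itself.
    """
    zeta, apg, t = beat.zeta, beat.apg, beat.t
    n = len(zeta)
    i_S = int(round(t_S * (n - 1)))
    hi = min(int(round((t_S + _NOTCH_WINDOW) * (n - 1))) + 1, n)
    inferred = False
    seg = zeta[i_S:hi]
    mins, _ = signal.find_peaks(-seg, prominence=1e-3)
    if len(mins) > 0:
        i_N = i_S + mins[0]
    else:
        # stiff, notchless pulse: most prominent APG maximum after S
        seg_apg = apg[i_S + 2:hi]
        if len(seg_apg) < 3:
            return (np.nan, np.nan, np.nan, np.nan, False, False, False)
        apeaks, props = signal.find_peaks(seg_apg, prominence=0.0)
        if len(apeaks) == 0:
            return (np.nan, np.nan, np.nan, np.nan, False, False, False)
        best = apeaks[int(np.argmax(props["prominences"]))]
        i_N = i_S + 2 + best
        inferred = True
    # diastolic peak: first local max after the notch
    after = zeta[i_N:]
    dpk, _ = signal.find_peaks(after, prominence=1e-3)
    if len(dpk) > 0:
        i_D = i_N + dpk[0]
        valid_D = True
    else:
        i_D = i_N
        valid_D = False
    return (float(t[i_N]), float(zeta[i_N]), float(t[i_D]), float(zeta[i_D]),
            True, valid_D, inferred)


def detect_apg_waves(beat: NormalizedBeat, t_limit: float = 0.9):
    """a-e waves of the APG as alternating extrema.

    ``a`` is the global APG maximum in early systole, ``b`` the following
    trough, and c, d, e the subsequent alternating extrema before
    ``t_limit``.  Missing later waves are simply absent from the result.
    """
    apg, t = beat.apg, beat.t
    n = len(apg)
    maxima = set(signal.find_peaks(apg)[0])
    minima = set(signal.find_peaks(-apg)[0])
    extrema = sorted(maxima | minima)
    times, amps = {}, {}
    if len(extrema) < 2:
        return times, amps
    i_a = int(np.argmax(apg))
    if i_a in (0, n - 1):
        cands = [i for i in maxima]
        if not cands:
            return times, amps
        i_a = min(cands, key=lambda i: -apg[i])
    times["a"], amps["a"] = float(t[i_a]), float(apg[i_a])
    limit = t_limit
    labels = ["b", "c", "d", "e"]
    want_min = True
    prev = i_a
    for label in labels:
        pool = minima if want_min else maxima
        nxt = [i for i in sorted(pool) if i > prev and t[i] <= limit]
        if not nxt:
            break
        idx = nxt[0]
        times[label], amps[label] = float(t[idx]), float(apg[idx])
        prev = idx
        want_min = not want_min
    return times, amps


def detect_fiducials(beat: NormalizedBeat,
                     apg_limit_after_notch: float = 0.1) -> FiducialSet:
    """Full fiducial set for one normalised beat; deterministic."""
    fid = FiducialSet()
    t_S, amp_S, valid_S, fallback = detect_systolic_peak(beat)
    fid.t_S, fid.amp_S = t_S, amp_S
    fid.valid["S"] = valid_S
    fid.systolic_fallback = fallback
    if valid_S:
        i_S = int(round(t_S * (len(beat.zeta) - 1)))
        if i_S > 0:
            i_W = int(np.argmax(beat.vpg[:i_S]))
            fid.t_W = float(beat.t[i_W])
            fid.valid["W"] = True
        (t_N, amp_N, t_D, amp_D, valid_N, valid_D,
         inferred) = detect_notch_diastolic(beat, t_S)
        fid.t_N, fid.amp_N, fid.t_D, fid.amp_D = t_N, amp_N, t_D, amp_D
        fid.valid["N"], fid.valid["D"] = valid_N, valid_D
        fid.notch_inferred = inferred
        t_limit = (t_N + apg_limit_after_notch) if valid_N else 0.9
    else:
        fid.valid["W"] = fid.valid["N"] = fid.valid["D"] = False
        t_limit = 0.9
    times, amps = detect_apg_waves(beat, t_limit=t_limit)
    fid.apg_times, fid.apg_amps = times, amps
    for w in "abcde":
        fid.valid[w] = w in times
    return fid
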