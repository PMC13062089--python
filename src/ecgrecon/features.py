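"""QRS detection (Pan-Tompkins), fiducial delineation and feature vectors.

The detector is the classic chain: 5-15 Hz band-pass, five-point derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds with a
200 ms refractory period and search-back.  Delineation then locates QRS
onset/end by amplitude/slope-threshold search outward from each R peak, the
P wave as a low-amplitude local maximum in a window before the R peak
(onset/end at 10 %-of-peak crossings) and the T end as the post-peak 10 %
crossing.

The per-record feature vector follows the conventional clinical schema:
mean RR interval, mean per-beat fiducial times relative to the R peak,
frontal-plane electrical axes from leads I and aVF, plus device metadata
(bandwidth, filtering).  Missing P-wave features (atrial fibrillation) are
encoded as a -1 sentinel with a binary ``p_present`` indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import InvalidArgumentError
from .types import ECGRecord, FiducialAnnotations

__all__ = ["pan_tompkins", "delineate", "electrical_axis",
           "build_feature_table", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = [
    "patient_id", "label", "bandwidth", "filtering", "rr_interval",
    "p_onset", "p_end", "qrs_onset", "qrs_end", "t_end",
    "p_axis", "qrs_axis", "t_axis", "p_present",
]

# Delineation windows and thresholds; amplitudes in mV.
QRS_SEARCH_S = 0.120
P_WINDOW_S = (0.300, 0.100)      # search [R-300 ms, R-100 ms]
T_WINDOW_START_S = 0.120
T_WINDOW_END_S = 0.500
P_MIN_AMP = 0.04                 # below this the beat has no P wave
P_MAX_AMP = 0.25                 # above this the deflection is not a P wave
QRS_AMP_FRACTION = 0.02          # onset/end where |x-base| falls below this * R amplitude
CROSSING_FRACTION = 0.10         # P/T boundary level relative to peak height


def pan_tompkins(signal: np.ndarray, fs: float,
                 refractory_s: float = 0.200) -> np.ndarray:
    """Detect R peaks on a single lead; returns strictly increasing indices."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise InvalidArgumentError("pan_tompkins expects a single-lead series")
    if len(signal) < 2 * fs:
        raise InvalidArgumentError("signal must be at least 2 s long")
    if np.ptp(signal) == 0:
        return np.array([], dtype=int)

    sos = sp_signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sp_signal.sosfiltfilt(sos, signal)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * fs / 8.0, mode="same")
    squared = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(refractory_s * fs))
    peaks, _ = sp_signal.find_peaks(mwi, distance=refractory)
    if len(peaks) == 0:
        return np.array([], dtype=int)

    spki = float(mwi[peaks].max()) / 3.0   # running signal-peak estimate
    npki = float(np.median(mwi)) / 2.0     # running noise-peak estimate
    threshold = npki + 0.25 * (spki - npki)
    accepted: list[int] = []
    for p in peaks:
        v = mwi[p]
        if v > threshold:
            accepted.append(int(p))
            spki = 0.125 * v + 0.875 * spki
        else:
            npki = 0.125 * v + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    # search-back: rescan long RR gaps at half threshold
    if len(accepted) >= 2:
        rr_mean = np.mean(np.diff(accepted))
        extra: list[int] = []
        for a, b in zip(accepted, accepted[1:]):
            if b - a > 1.66 * rr_mean:
                seg = peaks[(peaks > a + refractory) & (peaks < b - refractory)]
                if len(seg):
                    cand = seg[np.argmax(mwi[seg])]
                    if mwi[cand] > 0.5 * threshold:
                        extra.append(int(cand))
        accepted = sorted(accepted + extra)

    # refine each detection to the raw-signal maximum nearby
    half = int(round(0.040 * fs))
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(signal), p + half + 1)
        refined.append(lo + int(np.argmax(signal[lo:hi])))
    refined = sorted(set(refined))
    out = [refined[0]]
    for r in refined[1:]:
        if r - out[-1] >= refractory:
            out.append(r)
    return np.array(out, dtype=int)


def _walk_while_active(x: np.ndarray, slope: np.ndarray, start: int, stop: int,
                       amp_level: float, slope_level: float) -> int:
    """March from `start` toward `stop` until both |x| and |slope| settle.

    The slope condition carries the walk across the zero crossings between
    the R peak and the Q/S troughs, where amplitude alone would stop early.
    """
    step = 1 if stop >= start else -1
    i = start
    while i != stop and (abs(x[i]) > amp_level or abs(slope[i]) > slope_level):
        i += step
    return i


def delineate(record: ECGRecord, r_peaks: np.ndarray,
              lead: str = "II") -> FiducialAnnotations:
    """Estimate per-beat fiducials around the given R peaks.

    Beats whose search windows leave the record are dropped; P-wave fields
    are NaN when no credible P wave is found (local maximum with amplitude
    in [P_MIN_AMP, P_MAX_AMP] above the lead baseline).
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) == 0:
        raise InvalidArgumentError("delineation requires at least one R peak")
    fs = record.fs
    x0 = record.lead(lead)
    base = float(np.median(x0))
    x = x0 - base
    slope = np.gradient(x)
    n = len(x)
    rr_all = np.diff(r_peaks) / fs
    rows = {k: [] for k in ("r", "po", "pe", "qo", "qe", "te")}

    for bi, r in enumerate(r_peaks):
        rr = rr_all[bi] if bi < len(rr_all) else (rr_all[-1] if len(rr_all) else 1.0)
        qrs_half = int(round(QRS_SEARCH_S * fs))
        p_lo = r - int(round(P_WINDOW_S[0] * fs))
        p_hi = r - int(round(P_WINDOW_S[1] * fs))
        t_lo = r + int(round(T_WINDOW_START_S * fs))
        t_hi = r + int(round(min(T_WINDOW_END_S, 0.7 * rr) * fs))
        if p_lo < 0 or t_hi >= n or r - qrs_half < 0 or r + qrs_half >= n:
            continue  # window leaves the record

        # QRS onset/end: march outward from R until amplitude and slope both
        # settle below a small fraction of their in-complex maxima
        r_amp = abs(x[r])
        near = slice(max(0, r - int(0.04 * fs)), min(n, r + int(0.04 * fs) + 1))
        smax = np.abs(slope[near]).max()
        qo = _walk_while_active(x, slope, r, r - qrs_half,
                                QRS_AMP_FRACTION * r_amp, QRS_AMP_FRACTION * smax)
        qe = _walk_while_active(x, slope, r, r + qrs_half,
                                QRS_AMP_FRACTION * r_amp, QRS_AMP_FRACTION * smax)

        # P wave: low-amplitude local maximum closest to R inside the window
        seg = x[p_lo:p_hi]
        cand, _ = sp_signal.find_peaks(seg)
        cand = [c for c in cand if P_MIN_AMP <= seg[c] <= P_MAX_AMP]
        po, pe = np.nan, np.nan
        if cand:
            p_peak = p_lo + cand[-1]
            p_level = CROSSING_FRACTION * x[p_peak]
            i = p_peak
            while i > p_lo and x[i] > p_level:
                i -= 1
            po = float(i)
            i = p_peak
            while i < qo and x[i] > p_level:
                i += 1
            pe = float(i)
            if not (po < pe <= qo):
                po, pe = np.nan, np.nan

        # T end: 10 % crossing after the T peak
        t_seg = x[t_lo:t_hi]
        if len(t_seg) < 3:
            continue
        t_peak = t_lo + int(np.argmax(t_seg))
        t_level = CROSSING_FRACTION * x[t_peak]
        i = t_peak
        while i < t_hi - 1 and x[i] > t_level:
            i += 1
        te = i
        if not (qo < qe < te):
            continue
        rows["r"].append(r)
        rows["po"].append(po)
        rows["pe"].append(pe)
        rows["qo"].append(float(qo))
        rows["qe"].append(float(qe))
        rows["te"].append(float(te))

    if not rows["r"]:
        raise InvalidArgumentError("no beat could be delineated")
    return FiducialAnnotations(
        r_peaks=np.array(rows["r"], dtype=float),
        p_onset=np.array(rows["po"]), p_end=np.array(rows["pe"]),
        qrs_onset=np.array(rows["qo"]), qrs_end=np.array(rows["qe"]),
        t_end=np.array(rows["te"]),
    )


def electrical_axis(net_amp_lead_i: float, net_amp_avf: float) -> float:
    """Frontal-plane axis in degrees: atan2(aVF, I); 0 = leftward, +90 = inferior."""
    if net_amp_lead_i == 0 and net_amp_avf == 0:
        raise InvalidArgumentError("axis indeterminate: both net amplitudes zero")
    return float(np.degrees(np.arctan2(net_amp_avf, net_amp_lead_i)))


def _wave_axis(record: ECGRecord, lo: np.ndarray, hi: np.ndarray) -> float:
    """Axis from the signed area of a wave window in leads I and aVF."""
    i_sig, f_sig = record.lead("I"), record.lead("aVF")
    areas_i, areas_f = [], []
    for a, b in zip(lo, hi):
        if np.isnan(a) or np.isnan(b):
            continue
        a, b = int(a), int(b) + 1
        areas_i.append(i_sig[a:b].sum() / record.fs)
        areas_f.append(f_sig[a:b].sum() / record.fs)
    if not areas_i:
        return np.nan
    mi, mf = float(np.mean(areas_i)), float(np.mean(areas_f))
    if mi == 0 and mf == 0:
        return np.nan
    return electrical_axis(mi, mf)


def build_feature_table(records: list[ECGRecord],
                        annotations: list[FiducialAnnotations]) -> pd.DataFrame:
    """One feature row per record; columns follow ``FEATURE_COLUMNS``."""
    if len(records) != len(annotations):
        raise InvalidArgumentError("one annotation set per record required")
    rows = []
    for rec, ann in zip(records, annotations):
        fs = rec.fs
        r = ann.r_peaks
        rr = float(np.mean(np.diff(r)) / fs) if len(r) >= 2 else np.nan
        has_p = ~np.isnan(ann.p_onset)
        p_present = int(has_p.mean() >= 0.5) if len(has_p) else 0

        def rel(arr):
            vals = (arr - r) / fs
            vals = vals[~np.isnan(vals)]
            return float(np.mean(vals)) if len(vals) else np.nan

        p_onset, p_end = rel(ann.p_onset), rel(ann.p_end)
        qrs_onset, qrs_end, t_end = rel(ann.qrs_onset), rel(ann.qrs_end), rel(ann.t_end)

        p_axis = _wave_axis(rec, ann.p_onset, ann.p_end) if p_present else np.nan
        qrs_axis = _wave_axis(rec, ann.qrs_onset, ann.qrs_end)
        t_axis = _wave_axis(rec, ann.qrs_end, ann.t_end)

        def sentinel(v):
            return -1.0 if (v is None or not np.isfinite(v)) else float(v)

        # -1 marks any feature a record could not provide (absent P wave,
        # too few beats for an RR interval, missing metadata)
        rows.append({
            "patient_id": rec.patient_id,
            "label": rec.label,
            "bandwidth": sentinel(rec.meta.get("bandwidth", np.nan)),
            "filtering": rec.meta.get("filtering", 0),
            "rr_interval": sentinel(rr),
            "p_onset": sentinel(p_onset if p_present else np.nan),
            "p_end": sentinel(p_end if p_present else np.nan),
            "qrs_onset": sentinel(qrs_onset),
            "qrs_end": sentinel(qrs_end),
            "t_end": sentinel(t_end),
            "p_axis": sentinel(p_axis),
            "qrs_axis": sentinel(qrs_axis),
            "t_axis": sentinel(t_axis),
            "p_present": p_present,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
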