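"""Synthetic 12-lead ECG cohorts with analytically known fiducials.

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) on a single template
channel; the 12 leads are fixed linear projections of that template.  The
bump centers and widths are known, so every record carries exact ground-truth
fiducials -- the property that makes delineation and reconstruction testable
without real data.  Rhythm classes are realized through the RR-interval
process: periodic for the three sinus classes (bradycardia < 60 bpm, normal,
tachycardia > 100 bpm), i.i.d. log-normal RR with no P wave for atrial
fibrillation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sp_signal

from .errors import InvalidArgumentError
from .types import (
    STANDARD_LEADS, RHYTHM_CLASSES, ECGRecord, FiducialAnnotations,
    NoiseSpec, CohortSpec, ObservationMask,
)

__all__ = [
    "generate_clean_ecg", "add_noise", "simulate_missing", "generate_cohort",
    "LEAD_GAINS", "fisher_yates_select",
]

# Fixed projection gains of the template beat onto the 12 leads.  Lead II has
# the largest gain so the annotated R peak is the lead-II maximum.
LEAD_GAINS: dict[str, float] = {
    "I": 0.6, "II": 1.0, "III": 0.4, "aVR": -0.8, "aVL": 0.15, "aVF": 0.7,
    "V1": -0.35, "V2": 0.5, "V3": 0.75, "V4": 0.95, "V5": 0.85, "V6": 0.65,
}

# AF RR process: log-normal with sigma chosen so CV(RR) ~ 0.15.
AF_RR_SIGMA = 0.15


def _wave_params(rr: float, with_p: bool) -> list[tuple[str, float, float, float]]:
    """(name, center_s rel. R, width_s, amplitude_mV) for one beat.

    The P center and the T center/width scale with the RR interval so that
    morphology stays physiologically ordered from 20 to 300 bpm.
    """
    waves = []
    if with_p:
        p_center = -max(0.19 * np.sqrt(rr), 0.125)
        waves.append(("P", p_center, 0.015, 0.15))
    t_center = min(0.11 + 0.19 * rr, 0.36)
    t_width = 0.018 + 0.014 * min(rr, 1.0)
    waves += [
        ("Q", -0.040, 0.010, -0.10),
        ("R", 0.000, 0.012, 1.00),
        ("S", 0.035, 0.010, -0.20),
        ("T", t_center, t_width, 0.30),
    ]
    return waves


def _beat_fiducials(r_time: float, rr: float, with_p: bool) -> dict[str, float]:
    """Analytic bump boundaries (center +/- 3 widths) in seconds."""
    waves = {w[0]: w for w in _wave_params(rr, with_p)}
    fid = {
        "qrs_onset": r_time + waves["Q"][1] - 3 * waves["Q"][2],
        "qrs_end": r_time + waves["S"][1] + 3 * waves["S"][2],
        "t_end": r_time + waves["T"][1] + 3 * waves["T"][2],
    }
    if with_p:
        fid["p_onset"] = r_time + waves["P"][1] - 3 * waves["P"][2]
        fid["p_end"] = r_time + waves["P"][1] + 3 * waves["P"][2]
    else:
        fid["p_onset"] = np.nan
        fid["p_end"] = np.nan
    return fid


def generate_clean_ecg(duration_s: float, fs: float, heart_rate: float,
                       rhythm: str = "sinus_rhythm", seed: int = 0,
                       ) -> tuple[ECGRecord, FiducialAnnotations]:
    """Generate one noise-free 12-lead record with exact fiducials.

    For sinus rhythms the RR interval is a constant 60/heart_rate s; for
    atrial fibrillation RR intervals are i.i.d. log-normal (median
    60/heart_rate, sigma 0.15 on the log scale) and the P bump is omitted.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and sampling frequency must be positive")
    if not 20 <= heart_rate <= 300:
        raise InvalidArgumentError("heart_rate must lie in [20, 300] bpm")
    if rhythm not in RHYTHM_CLASSES:
        raise InvalidArgumentError(f"unknown rhythm class {rhythm!r}")
    rng = np.random.Generator(np.random.MT19937(seed))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    with_p = rhythm != "atrial_fibrillation"
    base_rr = 60.0 / heart_rate

    # Beat times: start at 0.35 s so the first P wave fits in the record.
    r_times: list[float] = []
    rr_list: list[float] = []
    pos = 0.35
    while pos < duration_s + base_rr:
        if rhythm == "atrial_fibrillation":
            rr = base_rr * np.exp(AF_RR_SIGMA * rng.standard_normal())
        else:
            rr = base_rr
        r_times.append(pos)
        rr_list.append(rr)
        pos += rr

    template = np.zeros(n)
    fid_rows = []
    for r_time, rr in zip(r_times, rr_list):
        for _, center, width, amp in _wave_params(rr, with_p):
            c = r_time + center
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            template[lo:hi] += amp * np.exp(-((tt - c) ** 2) / (2 * width ** 2))
        fid = _beat_fiducials(r_time, rr, with_p)
        r_idx = int(round(r_time * fs))
        if r_idx < 0 or r_idx >= n:
            continue
        start = fid["p_onset"] if with_p else fid["qrs_onset"]
        if start * fs < 0 or fid["t_end"] * fs >= n:
            continue  # beat not fully inside the record
        fid_rows.append((r_idx, fid))

    gains = np.array([LEAD_GAINS[name] for name in STANDARD_LEADS])
    sig = template[:, None] * gains[None, :]
    record = ECGRecord(signal=sig, fs=fs, lead_names=STANDARD_LEADS,
                       patient_id="synthetic", label=rhythm,
                       meta={"bandwidth": 40.0, "filtering": 0})

    def col(key):
        return np.array([np.round(f[key] * fs) if np.isfinite(f[key]) else np.nan
                         for _, f in fid_rows])

    ann = FiducialAnnotations(
        r_peaks=np.array([r for r, _ in fid_rows], dtype=float),
        p_onset=col("p_onset"), p_end=col("p_end"),
        qrs_onset=col("qrs_onset"), qrs_end=col("qrs_end"), t_end=col("t_end"),
    )
    return record, ann


def add_noise(record: ECGRecord, spec: NoiseSpec) -> ECGRecord:
    """Add baseline wander + powerline + band-limited EMG + white noise.

    Deterministic given (record, spec); phases and noise draws stream from
    ``spec.seed``.
    """
    spec.validate(record.fs)
    rng = np.random.Generator(np.random.MT19937(spec.seed))
    n, n_leads = record.signal.shape
    t = np.arange(n) / record.fs
    out = record.signal.copy()

    phases_bw = rng.uniform(0, 2 * np.pi, size=n_leads)
    phases_pl = rng.uniform(0, 2 * np.pi, size=n_leads)
    if spec.baseline_wander_amp > 0:
        out += spec.baseline_wander_amp * np.sin(
            2 * np.pi * spec.baseline_wander_freq * t[:, None] + phases_bw)
    if spec.powerline_amp > 0:
        out += spec.powerline_amp * np.sin(
            2 * np.pi * spec.powerline_freq * t[:, None] + phases_pl)
    if spec.emg_amp > 0:
        lo, hi = spec.emg_passband
        hi = min(hi, 0.45 * record.fs)
        raw = rng.standard_normal((n, n_leads))
        sos = sp_signal.butter(2, [lo, hi], btype="bandpass",
                               fs=record.fs, output="sos")
        emg = sp_signal.sosfiltfilt(sos, raw, axis=0)
        std = emg.std(axis=0)
        std[std == 0] = 1.0
        out += spec.emg_amp * emg / std
    if spec.white_sigma > 0:
        out += spec.white_sigma * rng.standard_normal((n, n_leads))
    return record.copy_with(signal=out)


def fisher_yates_select(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Select k distinct indices from [0, n) by a partial Fisher-Yates shuffle."""
    idx = np.arange(n)
    for i in range(k):
        j = i + int(rng.integers(n - i))
        idx[i], idx[j] = idx[j], idx[i]
    return idx[:k]


def _place_blocks(t_len: int, lengths: list[int],
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Place blocks of the given lengths in [0, t_len) without overlap."""
    total = sum(lengths)
    free = t_len - total
    m = len(lengths)
    if free < 0:
        raise InvalidArgumentError("blocks do not fit in the record")
    # distinct sorted draws from [0, free + m) map to non-negative gaps
    draws = np.sort(fisher_yates_select(free + m, m, rng))
    gaps = np.diff(np.concatenate(([-1], draws))) - 1
    spans = []
    pos = 0
    for gap, length in zip(gaps, lengths):
        pos += int(gap)
        spans.append((pos, pos + length))
        pos += length
    return spans


def simulate_missing(record: ECGRecord, ratio: float, mode: str = "segments",
                     segment_len: int = 250, seed: int = 0,
                     per_lead: bool = False,
                     ) -> tuple[ECGRecord, ObservationMask]:
    """Zero out a fraction of the record and return it with its mask.

    ``samples`` mode drops exactly round(ratio * T) individual time indices
    chosen without replacement by a partial Fisher-Yates shuffle of a
    Mersenne-Twister stream; ``segments`` mode drops non-overlapping blocks
    of ``segment_len`` samples (plus one shorter block when the target count
    is not a multiple) until the same count is reached.  The mask is shared
    across leads unless ``per_lead`` is set.
    """
    if not 0 <= ratio < 1:
        raise InvalidArgumentError("missing ratio must lie in [0, 1)")
    if mode not in ("samples", "segments"):
        raise InvalidArgumentError(f"unknown missingness mode {mode!r}")
    if mode == "segments" and segment_len < 1:
        raise InvalidArgumentError("segment_len must be >= 1")
    t_len, n_leads = record.signal.shape
    rng = np.random.Generator(np.random.MT19937(seed))
    k = int(round(ratio * t_len))
    mask = np.ones((t_len, n_leads))

    def column_mask() -> np.ndarray:
        col = np.ones(t_len)
        if k == 0:
            return col
        if mode == "samples":
            col[fisher_yates_select(t_len, k, rng)] = 0.0
        else:
            n_full, rem = divmod(k, segment_len)
            lengths = [segment_len] * n_full + ([rem] if rem else [])
            for lo, hi in _place_blocks(t_len, lengths, rng):
                col[lo:hi] = 0.0
        return col

    if per_lead:
        for li in range(n_leads):
            mask[:, li] = column_mask()
    else:
        mask[:] = column_mask()[:, None]

    masked = record.copy_with(signal=record.signal * mask)
    return masked, ObservationMask(mask=mask)


def generate_cohort(spec: CohortSpec) -> list[tuple[ECGRecord, FiducialAnnotations, str]]:
    """Generate ``spec.n_patients`` labeled records with known fiducials.

    Labels are drawn from the class priors; heart rates uniformly from each
    class's range, so the label is recoverable from RR statistics (mean RR
    maps back into the class range; AF shows irregular RR and no P wave).
    """
    spec.validate()
    rng = np.random.Generator(np.random.MT19937(spec.seed))
    priors = np.array([spec.class_priors.get(c, 0.0) for c in RHYTHM_CLASSES])
    labels = rng.choice(len(RHYTHM_CLASSES), size=spec.n_patients, p=priors)
    cohort = []
    for i, li in enumerate(labels):
        label = RHYTHM_CLASSES[li]
        lo, hi = spec.hr_ranges[label]
        hr = rng.uniform(lo, hi)
        sub_seed = int(rng.integers(2 ** 31))
        record, ann = generate_clean_ecg(spec.duration_s, spec.fs, hr,
                                         rhythm=label, seed=sub_seed)
        record.patient_id = f"P{i:05d}"
        record.label = label
        cohort.append((record, ann, label))
    return cohort
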