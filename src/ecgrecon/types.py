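"""Core in-memory containers for 12-lead ECG records and their annotations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError

STANDARD_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

RHYTHM_CLASSES: tuple[str, ...] = (
    "sinus_rhythm", "sinus_bradycardia", "sinus_tachycardia",
    "atrial_fibrillation",
)


@dataclass
class ECGRecord:
    """A T x L signal matrix with sampling metadata.

    ``signal`` is in millivolts unless ``normalized`` is set, in which case
    every entry lies in [0, 1] and ``norm_min``/``norm_max`` hold the
    per-lead affine parameters needed to invert the scaling.
    """

    signal: np.ndarray                       # (T, L)
    fs: float
    lead_names: tuple[str, ...] = STANDARD_LEADS
    patient_id: str = ""
    label: str | None = None
    normalized: bool = False
    norm_min: np.ndarray | None = None       # (L,)
    norm_max: np.ndarray | None = None       # (L,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise InvalidArgumentError("signal must be a T x L matrix")
        if self.fs <= 0:
            raise InvalidArgumentError("sampling frequency must be positive")
        if self.signal.shape[0] < 1:
            raise InvalidArgumentError("record must contain at least one sample")
        if len(self.lead_names) != self.signal.shape[1]:
            raise InvalidArgumentError("lead_names length must equal signal columns")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise InvalidArgumentError("lead names must be unique")
        if self.normalized:
            if self.signal.min() < -1e-9 or self.signal.max() > 1 + 1e-9:
                raise InvalidArgumentError("normalized record has entries outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, self.lead_names.index(name)]

    def copy_with(self, **kwargs) -> "ECGRecord":
        out = replace(self, **kwargs)
        if "signal" in kwargs:
            out.signal = np.asarray(kwargs["signal"], dtype=np.float64)
        return out


@dataclass
class FiducialAnnotations:
    """Per-beat landmark sample indices.

    All arrays have one entry per beat; P-wave fields are NaN for beats
    without a P wave (atrial fibrillation).  Indices are 0-based samples;
    time in seconds is index / fs.
    """

    r_peaks: np.ndarray
    p_onset: np.ndarray
    p_end: np.ndarray
    qrs_onset: np.ndarray
    qrs_end: np.ndarray
    t_end: np.ndarray

    def __post_init__(self):
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.float64)
        for name in ("p_onset", "p_end", "qrs_onset", "qrs_end", "t_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.r_peaks)
        for name in ("p_onset", "p_end", "qrs_onset", "qrs_end", "t_end"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError("annotation arrays must have one entry per beat")
        self.validate_ordering()

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks)

    def validate_ordering(self) -> None:
        """p_onset < p_end <= qrs_onset < qrs_end < t_end for every beat."""
        po, pe = self.p_onset, self.p_end
        has_p = ~np.isnan(po)
        if np.any(po[has_p] >= pe[has_p]) or np.any(pe[has_p] > self.qrs_onset[has_p]):
            raise InvalidArgumentError("P-wave fiducials out of order")
        if np.any(self.qrs_onset >= self.qrs_end) or np.any(self.qrs_end >= self.t_end):
            raise InvalidArgumentError("QRS/T fiducials out of order")


@dataclass
class ObservationMask:
    """Binary T x L matrix; 1 = observed, 0 = missing. X_obs = M * X."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise InvalidArgumentError("mask entries must be 0 or 1")
        self.mask = self.mask.astype(np.float64)

    @property
    def missing_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())

    def apply(self, signal: np.ndarray) -> np.ndarray:
        return signal * self.mask


@dataclass
class NoiseSpec:
    """Mixed-noise recipe: baseline wander + powerline + EMG + white noise."""

    baseline_wander_amp: float = 0.1      # mV
    baseline_wander_freq: float = 0.3     # Hz
    powerline_amp: float = 0.05           # mV
    powerline_freq: float = 50.0          # Hz (50 or 60)
    emg_amp: float = 0.03                 # mV
    emg_passband: tuple[float, float] = (20.0, 100.0)
    white_sigma: float = 0.02             # mV
    seed: int = 0

    def validate(self, fs: float) -> None:
        for amp in (self.baseline_wander_amp, self.powerline_amp,
                    self.emg_amp, self.white_sigma):
            if amp < 0:
                raise InvalidArgumentError("noise amplitudes must be non-negative")
        for f in (self.baseline_wander_freq, self.powerline_freq,
                  self.emg_passband[0]):
            if f >= fs / 2:
                raise InvalidArgumentError(
                    f"noise frequency {f} Hz at or above Nyquist ({fs / 2} Hz)")


# Heart-rate ranges (bpm) per rhythm class; sinus ranges are disjoint with
# margins so the generating class is recoverable from mean RR alone.
DEFAULT_HR_RANGES: dict[str, tuple[float, float]] = {
    "sinus_rhythm": (62.0, 98.0),
    "sinus_bradycardia": (40.0, 58.0),
    "sinus_tachycardia": (102.0, 150.0),
    "atrial_fibrillation": (60.0, 140.0),
}


@dataclass
class CohortSpec:
    """Study-cohort recipe: class mix and per-class heart-rate ranges."""

    n_patients: int
    class_priors: dict[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in RHYTHM_CLASSES})
    hr_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HR_RANGES))
    duration_s: float = 10.0
    fs: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise InvalidArgumentError("n_patients must be positive")
        priors = np.array([self.class_priors.get(c, 0.0) for c in RHYTHM_CLASSES])
        if (priors < 0).any() or abs(priors.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("class priors must be non-negative and sum to 1")
        lo, hi = self.hr_ranges["sinus_bradycardia"]
        if hi >= 60:
            raise InvalidArgumentError("bradycardia HR range must lie below 60 bpm")
        lo, hi = self.hr_ranges["sinus_tachycardia"]
        if lo <= 100:
            raise InvalidArgumentError("tachycardia HR range must lie above 100 bpm")
        sinus = ["sinus_bradycardia", "sinus_rhythm", "sinus_tachycardia"]
        spans = sorted(self.hr_ranges[c] for c in sinus)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            if h1 >= l2:
                raise InvalidArgumentError("sinus HR ranges must not overlap")
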