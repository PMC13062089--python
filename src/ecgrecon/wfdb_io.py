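"""WFDB-dialect record I/O, min-max normalization, and patient-level splits.

Implements the classic PhysioBank header (.hea) / signal (.dat) pair for
storage format 16 only (interleaved little-endian 16-bit integers).  Other
format codes are rejected on read.  Physical units are recovered as
(stored - baseline) / gain millivolts and every signal's 16-bit signed
checksum is verified.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CorruptRecordError, DegenerateLeadError, FormatError, InvalidArgumentError,
)
from .types import ECGRecord

__all__ = ["RecordHeader", "SignalDescriptor", "SplitAssignment",
           "read_record", "write_record", "normalize", "denormalize",
           "patient_split"]

DEFAULT_GAIN = 200.0  # adu per mV, the common PhysioBank default


@dataclass
class SignalDescriptor:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    units: str
    initial_value: int
    checksum: int
    block_size: int
    description: str = ""


@dataclass
class RecordHeader:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[SignalDescriptor] = field(default_factory=list)
    comments: list[str] = field(default_factory=list)


def _signed16(value: int) -> int:
    value &= 0xFFFF
    return value - 0x10000 if value >= 0x8000 else value


def _checksum(samples: np.ndarray) -> int:
    return _signed16(int(samples.astype(np.int64).sum()))


def write_record(record: ECGRecord, directory: str,
                 gain: float = DEFAULT_GAIN) -> RecordHeader:
    """Write ``record`` as a format-16 .hea/.dat pair named by its patient id."""
    if gain <= 0:
        raise InvalidArgumentError("gain must be positive")
    if not np.isfinite(record.signal).all():
        raise InvalidArgumentError("cannot store non-finite samples")
    name = record.patient_id or "record"
    os.makedirs(directory, exist_ok=True)
    stored = np.round(record.signal * gain).astype(np.int64)
    if stored.size and (stored.max() > 32767 or stored.min() < -32768):
        raise InvalidArgumentError("signal exceeds 16-bit range at this gain")
    stored = stored.astype(np.int16)
    n_samples, n_sig = record.signal.shape

    dat_name = f"{name}.dat"
    header = RecordHeader(record_name=name, n_sig=n_sig, fs=record.fs,
                          n_samples=n_samples)
    for li, lead in enumerate(record.lead_names):
        col = stored[:, li]
        header.signals.append(SignalDescriptor(
            file_name=dat_name, fmt=16, gain=gain, baseline=0, units="mV",
            initial_value=int(col[0]) if n_samples else 0,
            checksum=_checksum(col), block_size=0, description=lead,
        ))
    if record.label:
        header.comments.append(f"label: {record.label}")
    for key in ("bandwidth", "filtering"):
        if key in record.meta:
            header.comments.append(f"{key}: {record.meta[key]}")

    lines = [f"{name} {n_sig} {record.fs:g} {n_samples}"]
    for sd in header.signals:
        lines.append(
            f"{sd.file_name} {sd.fmt} {sd.gain:g}({sd.baseline})/{sd.units} "
            f"16 0 {sd.initial_value} {sd.checksum} {sd.block_size} {sd.description}"
        )
    lines += [f"# {c}" for c in header.comments]
    with open(os.path.join(directory, f"{name}.hea"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    if n_samples:
        stored.reshape(-1).tofile(os.path.join(directory, dat_name))
    else:
        open(os.path.join(directory, dat_name), "wb").close()
    return header


def _parse_header(path: str) -> RecordHeader:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    first = lines[0].split()
    if len(first) < 4:
        raise FormatError("header record line needs: name n_sig fs n_samples")
    header = RecordHeader(record_name=first[0], n_sig=int(first[1]),
                          fs=float(first[2]), n_samples=int(first[3]))
    body = lines[1:]
    for ln in body[: header.n_sig]:
        parts = ln.split()
        gain_field = parts[2]
        if "(" in gain_field:
            g, rest = gain_field.split("(")
            baseline = int(rest.split(")")[0])
        else:
            g, baseline = gain_field.split("/")[0], 0
        units = gain_field.split("/")[1] if "/" in gain_field else "mV"
        header.signals.append(SignalDescriptor(
            file_name=parts[0], fmt=int(parts[1]), gain=float(g),
            baseline=baseline, units=units, initial_value=int(parts[5]),
            checksum=int(parts[6]), block_size=int(parts[7]),
            description=" ".join(parts[8:]),
        ))
    if len(header.signals) != header.n_sig:
        raise FormatError("header lists fewer signal lines than n_sig")
    header.comments = [ln.lstrip("# ").strip() for ln in body[header.n_sig:]
                       if ln.startswith("#")]
    return header


def read_record(path: str) -> tuple[ECGRecord, RecordHeader]:
    """Read a .hea/.dat pair; ``path`` may omit the .hea suffix."""
    hea_path = path if path.endswith(".hea") else path + ".hea"
    header = _parse_header(hea_path)
    for sd in header.signals:
        if sd.fmt != 16:
            raise FormatError(
                f"storage format {sd.fmt} not supported (format 16 only)")
    dat_path = os.path.join(os.path.dirname(hea_path), header.signals[0].file_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size != header.n_samples * header.n_sig:
        raise FormatError(
            f"signal file holds {raw.size} samples, header says "
            f"{header.n_samples * header.n_sig}")
    stored = raw.reshape(header.n_samples, header.n_sig)
    physical = np.empty(stored.shape, dtype=np.float64)
    for li, sd in enumerate(header.signals):
        col = stored[:, li]
        if _checksum(col) != sd.checksum:
            raise CorruptRecordError(
                f"checksum mismatch on signal {sd.description or li}")
        physical[:, li] = (col.astype(np.float64) - sd.baseline) / sd.gain
    label = None
    meta = {}
    for c in header.comments:
        if c.startswith("label:"):
            label = c.split(":", 1)[1].strip()
        elif c.startswith(("bandwidth:", "filtering:")):
            key, val = c.split(":", 1)
            try:
                meta[key] = float(val) if key == "bandwidth" else int(val)
            except ValueError:
                pass
    record = ECGRecord(
        signal=physical, fs=header.fs,
        lead_names=tuple(sd.description or f"sig{i}"
                         for i, sd in enumerate(header.signals)),
        patient_id=header.record_name, label=label, meta=meta,
    )
    return record, header


def normalize(record: ECGRecord) -> ECGRecord:
    """Min-max scale each lead to [0, 1]; stores min/max for inversion."""
    lo = record.signal.min(axis=0)
    hi = record.signal.max(axis=0)
    if np.any(hi - lo <= 0):
        bad = [record.lead_names[i] for i in np.nonzero(hi - lo <= 0)[0]]
        raise DegenerateLeadError(f"constant lead(s) {bad}: zero range")
    scaled = (record.signal - lo) / (hi - lo)
    return record.copy_with(signal=scaled, normalized=True,
                            norm_min=lo, norm_max=hi)


def denormalize(record: ECGRecord) -> ECGRecord:
    if not record.normalized or record.norm_min is None:
        raise InvalidArgumentError("record is not normalized")
    sig = record.signal * (record.norm_max - record.norm_min) + record.norm_min
    return record.copy_with(signal=sig, normalized=False,
                            norm_min=None, norm_max=None)


@dataclass
class SplitAssignment:
    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, partition: str) -> list[str]:
        return [pid for pid, p in self.assignment.items() if p == partition]


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def patient_split(patient_ids: list[str],
                  fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> SplitAssignment:
    """Shuffle patients and partition into train/validation/test.

    Test and validation counts are rounded half-away-from-zero from their
    fractions; the remainder is the training set.  All records of a patient
    therefore share a partition by construction.
    """
    if len(set(patient_ids)) != len(patient_ids):
        raise InvalidArgumentError("patient ids must be unique")
    fr = np.asarray(fractions, dtype=float)
    if (fr <= 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("fractions must be positive and sum to 1")
    rng = np.random.Generator(np.random.MT19937(seed))
    ids = list(patient_ids)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_test = _round_half_away(fractions[2] * n)
    n_val = _round_half_away(fractions[1] * n)
    assignment: dict[str, str] = {}
    for pid in shuffled[:n_test]:
        assignment[pid] = "test"
    for pid in shuffled[n_test:n_test + n_val]:
        assignment[pid] = "validation"
    for pid in shuffled[n_test + n_val:]:
        assignment[pid] = "train"
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions),
                           seed=seed)
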