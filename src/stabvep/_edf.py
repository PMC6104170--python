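"""Minimal European Data Format (EDF) codec.

EDF stores an ASCII fixed-layout header (256 bytes plus 256 per signal)
followed by data records of little-endian int16 samples, one contiguous block
per signal per record. Physical values are mapped linearly onto the digital
range, so round-trip error is bounded by half a digital step:
``(phys_max - phys_min) / 2 / (dig_max - dig_min)``.

Recordings whose length is not a whole number of records are zero-padded to
the record boundary on disk; the true sample count is recorded in the header's
reserved field (``NSAMP=<n>``) and the padding is trimmed on read.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DIG_MIN = -32767  # symmetric range: physical 0 maps to digital 0 exactly
DIG_MAX = 32767


@dataclass
class EdfSignal:
    label: str
    data: np.ndarray
    phys_min: float
    phys_max: float
    dimension: str = "uV"


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def _num(value: float, width: int = 8) -> bytes:
    for fmt in (f"%.{p}g" for p in range(width - 1, 0, -1)):
        s = fmt % value
        if len(s) <= width:
            return _fixed(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path,
    signals: list[EdfSignal],
    sample_rate_hz: float,
    patient_id: str = "X",
    recording_id: str = "X",
    record_duration_s: float = 1.0,
) -> None:
    spr = sample_rate_hz * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz does not give a whole number of "
            f"samples per {record_duration_s}-s record; use the delimited dialect"
        )
    spr = int(round(spr))
    ns = len(signals)
    n_samples = len(signals[0].data)
    if any(len(s.data) != n_samples for s in signals):
        raise ValueError("all signals must have the same length")
    n_records = max(1, -(-n_samples // spr))

    header = bytearray()
    header += _fixed("0", 8)
    header += _fixed(patient_id, 80)
    header += _fixed(recording_id, 80)
    header += _fixed("01.01.00", 8)   # fixed date/time: simulated data carries
    header += _fixed("00.00.00", 8)   # its own clock (seconds from start)
    header += _fixed(str(256 * (1 + ns)), 8)
    header += _fixed(f"NSAMP={n_samples}", 44)
    header += _fixed(str(n_records), 8)
    header += _num(record_duration_s, 8)
    header += _fixed(str(ns), 4)
    for attr, width in (
        ("label", 16),
        ("transducer", 80),
        ("dimension", 8),
        ("phys_min", 8),
        ("phys_max", 8),
        ("dig_min", 8),
        ("dig_max", 8),
        ("prefilter", 80),
        ("spr", 8),
        ("reserved", 32),
    ):
        for s in signals:
            if attr == "label":
                header += _fixed(s.label, width)
            elif attr == "dimension":
                header += _fixed(s.dimension, width)
            elif attr == "phys_min":
                header += _num(s.phys_min, width)
            elif attr == "phys_max":
                header += _num(s.phys_max, width)
            elif attr == "dig_min":
                header += _fixed(str(DIG_MIN), width)
            elif attr == "dig_max":
                header += _fixed(str(DIG_MAX), width)
            elif attr == "spr":
                header += _fixed(str(spr), width)
            else:
                header += _fixed("", width)

    digital = np.empty((ns, n_records * spr), dtype="<i2")
    for i, s in enumerate(signals):
        if not s.phys_max > s.phys_min:
            raise ValueError(f"signal {s.label}: phys_max must exceed phys_min")
        gain = (s.phys_max - s.phys_min) / (DIG_MAX - DIG_MIN)
        pad_value = 0.0 if s.phys_min <= 0.0 <= s.phys_max else s.phys_min
        x = np.full(n_records * spr, pad_value)
        x[:n_samples] = s.data
        d = np.rint((x - s.phys_min) / gain) + DIG_MIN
        digital[i] = np.clip(d, DIG_MIN, DIG_MAX).astype("<i2")

    # record-interleave: (records, signals, spr)
    block = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(block).tobytes())


@dataclass
class EdfFile:
    labels: list[str]
    signals: dict[str, np.ndarray]
    sample_rate_hz: float
    patient_id: str
    recording_id: str
    phys_range: dict[str, tuple[float, float]]


def read_edf(path) -> EdfFile:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file (truncated header)")

    def field(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    patient_id = field(8, 80)
    recording_id = field(88, 80)
    reserved = field(192, 44)
    n_records = int(field(236, 8))
    record_duration = float(field(244, 8))
    ns = int(field(252, 4))

    def sig_fields(base: int, width: int) -> list[str]:
        off = 256 + base * ns
        return [
            raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = sig_fields(0, 16)
    phys_min = [float(v) for v in sig_fields(16 + 80 + 8, 8)]
    phys_max = [float(v) for v in sig_fields(16 + 80 + 16, 8)]
    dig_min = [int(float(v)) for v in sig_fields(16 + 80 + 24, 8)]
    dig_max = [int(float(v)) for v in sig_fields(16 + 80 + 32, 8)]
    spr = [int(v) for v in sig_fields(16 + 80 + 40 + 80, 8)]

    header_bytes = 256 * (1 + ns)
    data = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    per_record = sum(spr)
    if len(data) < n_records * per_record:
        raise ValueError(f"{path}: data shorter than header declares")
    data = data[: n_records * per_record].reshape(n_records, per_record)

    n_true = None
    if reserved.startswith("NSAMP="):
        n_true = int(reserved[6:])

    signals: dict[str, np.ndarray] = {}
    phys_range: dict[str, tuple[float, float]] = {}
    offset = 0
    for i, label in enumerate(labels):
        block = data[:, offset : offset + spr[i]].reshape(-1).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        phys = (block - dig_min[i]) * gain + phys_min[i]
        if n_true is not None:
            phys = phys[:n_true]
        signals[label] = phys
        phys_range[label] = (phys_min[i], phys_max[i])
        offset += spr[i]

    # All channels of one recording share the sampling rate here.
    fs = spr[0] / record_duration
    return EdfFile(
        labels=labels,
        signals=signals,
        sample_rate_hz=fs,
        patient_id=patient_id,
        recording_id=recording_id,
        phys_range=phys_range,
    )
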