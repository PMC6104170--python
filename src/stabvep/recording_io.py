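"""Read/write polysomnographic recordings, hypnograms and derived tables.

Two signal dialects are supported:

* ``EDF`` — European Data Format with channels ``EEG``, ``EMG``, ``TTL``
  (16-bit; EEG/EMG physical range ±2000 μV by default, TTL 0–1). Subject,
  condition and session start are carried in the recording-id header field.
* ``DELIMITED`` — plain text with header ``time_s,eeg_uv,emg_uv,ttl`` (comma
  or tab separated) at uniform time spacing.

Hypnograms are delimited tables with columns
``epoch_index,base_label[,wake_substate,beta_class]``.
"""
from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from .errors import ChannelMissingError, LabelParseError, TimeAxisError
from .recording import BetaClass, Condition, Hypnogram, Recording, WakeSubstate

#: default EEG/EMG physical full scale in μV (±) for EDF quantization
DEFAULT_PHYS_RANGE_UV = 2000.0

_BASE_TOKENS = {
    "W": "WAKE", "WAKE": "WAKE",
    "S": "SWS", "SWS": "SWS",
    "R": "REMS", "REMS": "REMS", "REM": "REMS",
    "U": "UNSCORED", "UNSCORED": "UNSCORED",
}
_SUBSTATE_TOKENS = {s: s for s in ("AW", "IW", "QW", "NOT_WAKE")}
_BETA_TOKENS = {s: s for s in ("LOW", "MID", "HIGH", "UNASSIGNED")}


def _infer_dialect(path, dialect: str | None) -> str:
    if dialect is not None:
        d = dialect.upper()
        if d not in ("EDF", "DELIMITED"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return d
    return "EDF" if str(path).lower().endswith(".edf") else "DELIMITED"


def _sep_of(path) -> str:
    with open(path, "r") as fh:
        return "\t" if "\t" in fh.readline() else ","


def read_recording(path, dialect: str | None = None) -> Recording:
    """Load a recording from EDF or delimited text.

    The sampling rate comes from the EDF header or, for delimited files, from
    the median spacing of the time column (relative jitter above 1e-6 is a
    format error). TTL is digitized at half the channel's physical range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_dialect(path, dialect) == "EDF":
        return _read_recording_edf(path)
    return _read_recording_delimited(path)


def _read_recording_edf(path: Path) -> Recording:
    f = _edf.read_edf(path)
    channels = {}
    for want in ("EEG", "EMG", "TTL"):
        match = [lab for lab in f.labels if lab.upper() == want]
        if not match:
            raise ChannelMissingError(f"{path}: channel {want!r} not found (has {f.labels})")
        channels[want] = match[0]
    pmin, pmax = f.phys_range[channels["TTL"]]
    ttl = (f.signals[channels["TTL"]] > (pmin + pmax) / 2.0).astype(float)
    meta = _parse_recording_id(f.recording_id)
    return Recording(
        eeg=f.signals[channels["EEG"]],
        emg=f.signals[channels["EMG"]],
        ttl=ttl,
        sample_rate_hz=f.sample_rate_hz,
        session_start_zt_h=meta.get("zt", 2.0),
        subject_id=meta.get("subject", f.patient_id or "unknown"),
        condition=meta.get("condition", Condition.UNSPECIFIED),
    )


def _read_recording_delimited(path: Path) -> Recording:
    df = pd.read_csv(path, sep=_sep_of(path))
    cols = {c.strip().lower(): c for c in df.columns}
    aliases = {"time_s": ("time_s", "time"), "eeg_uv": ("eeg_uv", "eeg"),
               "emg_uv": ("emg_uv", "emg"), "ttl": ("ttl",)}
    found = {}
    for want, names in aliases.items():
        hit = next((cols[n] for n in names if n in cols), None)
        if hit is None:
            raise ChannelMissingError(f"{path}: column {want!r} missing (has {list(df.columns)})")
        found[want] = hit
    t = df[found["time_s"]].to_numpy(float)
    if len(t) < 2:
        raise TimeAxisError(f"{path}: need at least two samples to infer rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0 or np.max(np.abs(dt - med)) / med > 1e-6:
        raise TimeAxisError(f"{path}: non-uniform time axis (median spacing {med})")
    ttl_raw = df[found["ttl"]].to_numpy(float)
    near = np.minimum(np.abs(ttl_raw), np.abs(ttl_raw - 1.0))
    if (near > 1e-6).any():
        bad = ttl_raw[near > 1e-6][0]
        raise ValueError(f"{path}: ttl value {bad} is not 0 or 1")
    return Recording(
        eeg=df[found["eeg_uv"]].to_numpy(float),
        emg=df[found["emg_uv"]].to_numpy(float),
        ttl=(ttl_raw > 0.5).astype(float),
        sample_rate_hz=1.0 / med,
    )


def _parse_recording_id(text: str) -> dict:
    meta = {}
    for part in text.replace(";", " ").split():
        if "=" not in part:
            continue
        key, val = part.split("=", 1)
        if key == "SUBJ":
            meta["subject"] = val
        elif key == "COND":
            try:
                meta["condition"] = Condition(val)
            except ValueError:
                pass
        elif key == "ZT":
            try:
                meta["zt"] = float(val)
            except ValueError:
                pass
    return meta


def write_recording(
    rec: Recording,
    path,
    dialect: str | None = None,
    phys_range_uv: float = DEFAULT_PHYS_RANGE_UV,
    delimiter: str = ",",
) -> Path:
    """Write a recording; ``read_recording`` inverts it up to EDF quantization
    (max absolute error one half digital step of the ±``phys_range_uv`` scale)."""
    path = Path(path)
    if _infer_dialect(path, dialect) == "EDF":
        signals = [
            _edf.EdfSignal("EEG", rec.eeg, -phys_range_uv, phys_range_uv, "uV"),
            _edf.EdfSignal("EMG", rec.emg, -phys_range_uv, phys_range_uv, "uV"),
            _edf.EdfSignal("TTL", rec.ttl, 0.0, 1.0, ""),
        ]
        rid = f"SUBJ={rec.subject_id} COND={rec.condition} ZT={rec.session_start_zt_h:g}"
        _edf.write_edf(path, signals, rec.sample_rate_hz,
                       patient_id=rec.subject_id, recording_id=rid)
    else:
        t = np.arange(rec.n_samples) / rec.sample_rate_hz
        df = pd.DataFrame({
            "time_s": t,
            "eeg_uv": rec.eeg,
            "emg_uv": rec.emg,
            "ttl": rec.ttl.astype(int),
        })
        df.to_csv(path, sep=delimiter, index=False)
    return path


def read_hypnogram(path, epoch_length_s: float = 10.0) -> Hypnogram:
    """Parse a delimited hypnogram; unknown label tokens raise
    :class:`LabelParseError` naming the token and line."""
    path = Path(path)
    sep = _sep_of(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "base_label" not in cols:
        raise LabelParseError(f"{path}: no base_label column (has {list(df.columns)})")
    if "epoch_index" in cols:
        order = df[cols["epoch_index"]].astype(int).to_numpy()
        df = df.iloc[np.argsort(order, kind="stable")]

    def translate(column: str, tokens: dict) -> np.ndarray:
        out = []
        for row_pos, raw in zip(df.index, df[column]):
            token = str(raw).strip().upper()
            if token not in tokens:
                raise LabelParseError(
                    f"{path}: unknown label token {raw!r} on line {row_pos + 2}"
                )
            out.append(tokens[token])
        return np.array(out)

    base = translate(cols["base_label"], _BASE_TOKENS)
    substates = None
    if "wake_substate" in cols and df[cols["wake_substate"]].notna().all():
        substates = translate(cols["wake_substate"], _SUBSTATE_TOKENS)
    beta = None
    if "beta_class" in cols and df[cols["beta_class"]].notna().all():
        beta = translate(cols["beta_class"], _BETA_TOKENS)
    return Hypnogram(base, epoch_length_s=epoch_length_s,
                     wake_substates=substates, beta_classes=beta)


def write_hypnogram(hyp: Hypnogram, path, delimiter: str = ",") -> Path:
    path = Path(path)
    data = {"epoch_index": np.arange(hyp.n_epochs), "base_label": hyp.base_labels}
    if hyp.wake_substates is not None:
        data["wake_substate"] = hyp.wake_substates
    if hyp.beta_classes is not None:
        data["beta_class"] = hyp.beta_classes
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)
    return path


def write_epoch_table(table: pd.DataFrame, path, delimiter: str = ",") -> Path:
    """Write a per-epoch feature table with a stable column order and header."""
    path = Path(path)
    if os.path.isdir(path):
        raise IsADirectoryError(f"{path} is a directory")
    lead = [c for c in ("epoch_index", "base_label", "wake_substate",
                        "beta_class", "interval_label", "emg_rms") if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    table[lead + rest].to_csv(path, sep=delimiter, index=False)
    return path


def read_epoch_table(path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=delimiter or _sep_of(path))
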