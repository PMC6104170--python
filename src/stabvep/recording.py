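"""Core domain types: synchronized polysomnographic signals, hypnograms, stimulus trains.

Time convention: sample ``i`` occupies ``[i/fs, (i+1)/fs)``; all times are seconds
from recording start; sample indices are 0-based. Epochs are half-open
``[k*epoch_length_s, (k+1)*epoch_length_s)``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Condition(enum.StrEnum):
    SPONTANEOUS = "SPONTANEOUS"
    SLEEP_DISRUPTION = "SLEEP_DISRUPTION"
    UNSPECIFIED = "UNSPECIFIED"


class BaseState(enum.StrEnum):
    WAKE = "WAKE"
    SWS = "SWS"
    REMS = "REMS"
    UNSCORED = "UNSCORED"


class WakeSubstate(enum.StrEnum):
    AW = "AW"
    IW = "IW"
    QW = "QW"
    NOT_WAKE = "NOT_WAKE"


class BetaClass(enum.StrEnum):
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"
    UNASSIGNED = "UNASSIGNED"


#: The five effective vigilance states used throughout the analysis: WAKE is
#: always resolved to its EMG-defined substate.
EFFECTIVE_STATES = ("AW", "IW", "QW", "SWS", "REMS")


@dataclass
class Recording:
    """Synchronized EEG/EMG/TTL sample series (μV; TTL binary 0/1)."""

    eeg: np.ndarray
    emg: np.ndarray
    ttl: np.ndarray
    sample_rate_hz: float = 400.0
    session_start_zt_h: float = 2.0
    subject_id: str = "unknown"
    condition: Condition = Condition.UNSPECIFIED

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        self.ttl = np.asarray(self.ttl, dtype=float)
        self.condition = Condition(self.condition)
        self.validate()

    def validate(self) -> None:
        if not (len(self.eeg) == len(self.emg) == len(self.ttl)):
            raise ValueError(
                "eeg, emg and ttl must have identical length "
                f"(got {len(self.eeg)}, {len(self.emg)}, {len(self.ttl)})"
            )
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if len(self.ttl) and not np.isin(self.ttl, (0.0, 1.0)).all():
            raise ValueError("ttl samples must all be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels on a fixed 10-s (default) epoch grid.

    ``wake_substates``/``beta_classes`` are optional refinements; when present
    they are aligned 1:1 with ``base_labels``.
    """

    base_labels: np.ndarray
    epoch_length_s: float = 10.0
    wake_substates: np.ndarray | None = None
    beta_classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.base_labels = np.asarray(self.base_labels, dtype="U8")
        if self.wake_substates is not None:
            self.wake_substates = np.asarray(self.wake_substates, dtype="U8")
        if self.beta_classes is not None:
            self.beta_classes = np.asarray(self.beta_classes, dtype="U10")
        self.validate()

    def validate(self) -> None:
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        valid = {s.value for s in BaseState}
        bad = set(np.unique(self.base_labels)) - valid
        if bad:
            raise ValueError(f"unknown base labels: {sorted(bad)}")
        if self.wake_substates is not None:
            if len(self.wake_substates) != len(self.base_labels):
                raise ValueError("wake_substates length must match base_labels")
            wake = self.base_labels == BaseState.WAKE
            if (self.wake_substates[~wake] != WakeSubstate.NOT_WAKE).any():
                raise ValueError("non-WAKE epochs must carry substate NOT_WAKE")
            if (self.wake_substates[wake] == WakeSubstate.NOT_WAKE).any():
                raise ValueError("WAKE epochs must carry a substate other than NOT_WAKE")
        if self.beta_classes is not None and len(self.beta_classes) != len(self.base_labels):
            raise ValueError("beta_classes length must match base_labels")

    @property
    def n_epochs(self) -> int:
        return len(self.base_labels)

    def effective_labels(self) -> np.ndarray:
        """Per-epoch effective state: the EMG-defined substate for WAKE epochs,
        the base label otherwise. WAKE epochs without substates stay ``WAKE``."""
        eff = self.base_labels.copy()
        if self.wake_substates is not None:
            wake = self.base_labels == BaseState.WAKE
            eff[wake] = self.wake_substates[wake]
        return eff

    def epoch_of_time(self, t_s: float) -> int:
        return int(np.floor(t_s / self.epoch_length_s))


@dataclass
class StimulusTrain:
    """Onset times of a train of brief light pulses (seconds from recording start)."""

    onset_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    pulse_duration_s: float = 0.010
    nominal_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.onset_times_s = np.asarray(self.onset_times_s, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.pulse_duration_s <= 0:
            raise ValueError("pulse_duration_s must be positive")
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        if len(self.onset_times_s) > 1:
            gaps = np.diff(self.onset_times_s)
            if (gaps <= 0).any():
                raise ValueError("onset times must be strictly increasing")
            if (gaps < self.pulse_duration_s).any():
                raise ValueError("inter-onset interval shorter than pulse duration")

    @property
    def n_stimuli(self) -> int:
        return len(self.onset_times_s)


def extract_stimulus_train(rec: Recording) -> StimulusTrain:
    """Detect stimulus onsets from the binary TTL trace.

    An onset is the first sample of each high run (a 0→1 transition); a run
    beginning at sample 0 counts as an onset. Pulse duration is the modal high
    run length divided by the sampling rate. An all-zero TTL yields an empty
    train (not an error).
    """
    ttl = rec.ttl.astype(bool)
    if not ttl.any():
        return StimulusTrain(np.array([]), nominal_rate_hz=1.0)
    padded = np.concatenate(([False], ttl, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    run_lengths = ends - starts
    counts = np.bincount(run_lengths)
    modal_len = int(np.argmax(counts))
    fs = rec.sample_rate_hz
    rate = 1.0
    if len(starts) > 1:
        rate = 1.0 / float(np.median(np.diff(starts)) / fs)
    return StimulusTrain(
        onset_times_s=starts / fs,
        pulse_duration_s=modal_len / fs,
        nominal_rate_hz=rate,
    )
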