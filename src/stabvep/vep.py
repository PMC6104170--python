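"""State-sorted visual evoked potential (VEP) extraction and scoring.

Each stimulus contributes the EEG from 0.5 s before to 0.5 s after onset
(401 samples at 400 Hz, onset at the center sample). Trials are sorted by the
effective vigilance state (wake substate, SWS or REMS) of the epoch containing
the onset, optionally crossed with the epoch's beta class and 2-h analysis
interval, then averaged point-wise. VEP magnitude is the average potential
250 ms after onset minus the (negative) potential 150 ms after onset — read at
the nearest grid sample, which at 400 Hz is exact. No baseline correction is
applied by default (the magnitude is a within-waveform difference and is
offset-invariant); pre-stimulus-mean subtraction is available for display.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridError
from .recording import BaseState, Hypnogram, Recording, StimulusTrain

#: label given to trials falling in UNSCORED epochs
EXCLUDED = "EXCLUDED"


@dataclass
class VEPWaveform:
    """Average peri-stimulus potential for one trial group."""

    time_s: np.ndarray          # uniform grid, seconds relative to onset
    mean_uv: np.ndarray
    n_trials: int
    group_label: tuple | str = ""

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


def extract_peristimulus(
    rec: Recording,
    train: StimulusTrain,
    pre_s: float = 0.5,
    post_s: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """EEG segments around each onset.

    Returns ``(segments, kept_onset_samples, n_dropped)`` where ``segments``
    has one row per kept trial covering onset−pre_s … onset+post_s inclusive,
    and trials whose window crosses a recording boundary are dropped and
    tallied in ``n_dropped``.
    """
    fs = rec.sample_rate_hz
    k_pre = int(round(pre_s * fs))
    k_post = int(round(post_s * fs))
    onsets = np.rint(train.onset_times_s * fs).astype(int)
    keep = (onsets - k_pre >= 0) & (onsets + k_post < rec.n_samples)
    kept = onsets[keep]
    if len(kept) == 0:
        return np.empty((0, k_pre + k_post + 1)), kept, int((~keep).sum())
    idx = kept[:, None] + np.arange(-k_pre, k_post + 1)[None, :]
    return rec.eeg[idx], kept, int((~keep).sum())


def peristimulus_time_axis(sample_rate_hz: float, pre_s: float = 0.5, post_s: float = 0.5) -> np.ndarray:
    k_pre = int(round(pre_s * sample_rate_hz))
    k_post = int(round(post_s * sample_rate_hz))
    return np.arange(-k_pre, k_post + 1) / sample_rate_hz


def assign_trial_state(train: StimulusTrain, hyp: Hypnogram) -> np.ndarray:
    """Effective state of the epoch containing each onset (epochs half-open:
    an onset exactly on a boundary belongs to the later epoch). Trials in
    UNSCORED epochs or beyond the hypnogram get the EXCLUDED label."""
    eff = hyp.effective_labels()
    epochs = np.floor(train.onset_times_s / hyp.epoch_length_s).astype(int)
    labels = np.full(len(epochs), EXCLUDED, dtype="U10")
    ok = (epochs >= 0) & (epochs < len(eff))
    labels[ok] = eff[epochs[ok]]
    labels[labels == BaseState.UNSCORED] = EXCLUDED
    return labels


def average_vep(
    segments: np.ndarray,
    labels,
    sample_rate_hz: float,
    pre_s: float = 0.5,
    min_trials: int = 10,
    baseline_correct: bool = False,
) -> dict:
    """Point-wise mean waveform per group label.

    Groups with fewer than ``min_trials`` trials are omitted with a warning,
    never padded. Optional baseline correction subtracts each average's
    pre-stimulus mean (display only; magnitude is offset-invariant).
    """
    label_list = [label if isinstance(label, (str, tuple)) else str(label)
                  for label in labels]
    if len(label_list) != len(segments):
        raise ValueError("one label per trial required")
    n_cols = segments.shape[1] if len(segments) else 0
    time_s = np.arange(n_cols) / sample_rate_hz - pre_s
    out = {}
    for label in sorted(set(label_list) - {EXCLUDED}):
        mask = np.array([item == label for item in label_list], dtype=bool)
        rows = segments[mask]
        if len(rows) < min_trials:
            warnings.warn(
                f"group {label!r}: {len(rows)} trials < min_trials={min_trials}; omitted",
                stacklevel=2,
            )
            continue
        mean = rows.mean(axis=0)
        if baseline_correct:
            mean = mean - mean[time_s < 0].mean()
        out[label] = VEPWaveform(time_s=time_s, mean_uv=mean,
                                 n_trials=len(rows), group_label=label)
    return out


def vep_magnitude(
    w: VEPWaveform,
    neg_latency_s: float = 0.150,
    pos_latency_s: float = 0.250,
    search_halfwidth_s: float = 0.0,
) -> float:
    """Peak-to-peak score: potential at +250 ms minus potential at +150 ms.

    Latencies are read at the single nearest grid sample. A nonzero
    ``search_halfwidth_s`` instead takes the local minimum (negative lobe) and
    maximum (positive lobe) within ±halfwidth of the nominal latencies — a
    sensitivity variant, off by default.
    """
    fs = w.sample_rate_hz

    def value_at(latency: float, mode: str) -> float:
        i = int(round((latency - float(w.time_s[0])) * fs))
        if not 0 <= i < len(w.mean_uv):
            raise GridError(f"waveform grid does not cover +{latency*1e3:.0f} ms")
        if search_halfwidth_s > 0:
            h = int(round(search_halfwidth_s * fs))
            lo, hi = max(0, i - h), min(len(w.mean_uv), i + h + 1)
            window = w.mean_uv[lo:hi]
            return float(window.min() if mode == "neg" else window.max())
        return float(w.mean_uv[i])

    return value_at(pos_latency_s, "pos") - value_at(neg_latency_s, "neg")


def _interval_of(times_s: np.ndarray) -> np.ndarray:
    labels = np.full(len(times_s), "NONE", dtype="U4")
    labels[times_s < 6 * 3600] = "H56"
    labels[times_s < 4 * 3600] = "H34"
    labels[times_s < 2 * 3600] = "H12"
    return labels


def sort_and_average(
    rec: Recording,
    train: StimulusTrain,
    hyp: Hypnogram,
    features: pd.DataFrame | None = None,
    group_by: tuple[str, ...] = ("state",),
    min_trials: int = 10,
    baseline_correct: bool = False,
) -> tuple[dict, dict]:
    """Group trials by any of ``state``, ``beta_class``, ``interval`` and
    average each group.

    Returns ``(waveforms, exclusions)``; exclusions count boundary-dropped
    trials, trials in unscored epochs, and trials in groups below
    ``min_trials``, so that kept + excluded = total onsets.
    """
    allowed = {"state", "beta_class", "interval"}
    if not set(group_by) <= allowed:
        raise ValueError(f"group_by keys must be among {sorted(allowed)}")
    fs = rec.sample_rate_hz
    segments, kept_onsets, n_dropped = extract_peristimulus(rec, train)
    kept_times = kept_onsets / fs
    states = assign_trial_state(
        StimulusTrain(kept_times, train.pulse_duration_s, train.nominal_rate_hz), hyp
    ) if len(kept_times) else np.array([], dtype="U10")

    keys = {}
    if "state" in group_by:
        keys["state"] = states
    if "beta_class" in group_by:
        if features is None:
            raise ValueError("beta_class grouping requires the epoch feature table")
        epoch_idx = np.floor(kept_times / hyp.epoch_length_s).astype(int)
        beta = features.set_index("epoch_index")["beta_class"]
        keys["beta_class"] = np.array(
            [beta.get(e, "UNASSIGNED") for e in epoch_idx], dtype="U10"
        )
    if "interval" in group_by:
        keys["interval"] = _interval_of(kept_times)

    unscored = states == EXCLUDED
    labels = [
        EXCLUDED if unscored[i] else tuple(keys[k][i] for k in group_by)
        for i in range(len(kept_times))
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        waveforms = average_vep(segments, labels, fs, min_trials=min_trials,
                                baseline_correct=baseline_correct)
    n_kept = sum(w.n_trials for w in waveforms.values())
    exclusions = {
        "boundary": n_dropped,
        "unscored": int(unscored.sum()),
        "below_min_trials": len(kept_times) - int(unscored.sum()) - n_kept,
    }
    return waveforms, exclusions


def vep_table(
    rec: Recording,
    train: StimulusTrain,
    hyp: Hypnogram,
    features: pd.DataFrame | None = None,
    group_by: tuple[str, ...] = ("state",),
    min_trials: int = 10,
    **kwargs,
) -> pd.DataFrame:
    """One magnitude per requested group, long format with group columns,
    ``magnitude_uv`` and ``n_trials``."""
    waveforms, _ = sort_and_average(
        rec, train, hyp, features=features, group_by=group_by,
        min_trials=min_trials, **kwargs,
    )
    rows = []
    for label, w in sorted(waveforms.items()):
        row = dict(zip(group_by, label))
        row["magnitude_uv"] = vep_magnitude(w)
        row["n_trials"] = w.n_trials
        rows.append(row)
    return pd.DataFrame(rows, columns=[*group_by, "magnitude_uv", "n_trials"])
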