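"""Wake-substate classification and beta-power stratification.

Wake epochs are subdivided by EMG RMS percentiles computed across all WAKE
epochs of the recording: quiet wakefulness (QW) at or below the 33rd
percentile, active wakefulness (AW) at or above the 66th, intermediate (IW)
otherwise. Epochs of a given effective state are likewise stratified into
LOW (≤ 20th percentile) / HIGH (≥ 80th percentile) / MID beta-power classes,
percentiles taken over that state's epochs within the recording.

Percentiles use linear interpolation between order statistics (quantile q at
position 1 + (n−1)q), pinned so results are bit-reproducible. In the
degenerate all-ties case an epoch satisfying both the low and high conditions
takes the low class (QW, resp. LOW).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ClassificationError
from .recording import BaseState, BetaClass, Hypnogram, WakeSubstate


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile (the pinned convention for the package)."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


def classify_wake_substates(
    table: pd.DataFrame,
    hyp: Hypnogram,
    low_pct: float = 33.0,
    high_pct: float = 66.0,
) -> Hypnogram:
    """Return a new hypnogram with QW/IW/AW filled in for WAKE epochs.

    Thresholds are the ``low_pct`` and ``high_pct`` percentiles of per-epoch
    EMG RMS over all WAKE epochs of this recording. Requires at least three
    WAKE epochs.
    """
    n = len(table)
    base = hyp.base_labels[:n]
    rms = table["emg_rms"].to_numpy(float)
    wake = base == BaseState.WAKE
    if wake.sum() < 3:
        raise ClassificationError(
            f"need >=3 WAKE epochs to classify substates, found {int(wake.sum())}"
        )
    p_low = percentile(rms[wake], low_pct)
    p_high = percentile(rms[wake], high_pct)
    substates = np.full(n, WakeSubstate.NOT_WAKE, dtype="U8")
    substates[wake] = WakeSubstate.IW
    substates[wake & (rms >= p_high)] = WakeSubstate.AW
    substates[wake & (rms <= p_low)] = WakeSubstate.QW  # ties resolve to QW
    return Hypnogram(
        base_labels=base,
        epoch_length_s=hyp.epoch_length_s,
        wake_substates=substates,
        beta_classes=hyp.beta_classes[:n] if hyp.beta_classes is not None else None,
    )


def stratify_by_beta(
    table: pd.DataFrame,
    state: str,
    band: str = "beta",
    low_pct: float = 20.0,
    high_pct: float = 80.0,
) -> pd.DataFrame:
    """Fill ``beta_class`` for epochs of one effective state.

    Percentiles are computed over the ``power_<band>`` of that state's epochs
    only, within this recording; other states' classes are untouched. With
    fewer than five epochs of the state, stratification is skipped with a
    warning and the table returned unchanged.
    """
    out = table.copy()
    if "beta_class" not in out.columns:
        out["beta_class"] = BetaClass.UNASSIGNED
    eff = np.where(
        out["base_label"].to_numpy() == BaseState.WAKE,
        out["wake_substate"].to_numpy(),
        out["base_label"].to_numpy(),
    )
    sel = eff == state
    if sel.sum() < 5:
        warnings.warn(
            f"only {int(sel.sum())} epochs of {state}; beta stratification skipped",
            stacklevel=2,
        )
        return out
    power = out.loc[sel, f"power_{band}"].to_numpy(float)
    p_low = percentile(power, low_pct)
    p_high = percentile(power, high_pct)
    cls = np.full(int(sel.sum()), BetaClass.MID, dtype="U10")
    cls[power >= p_high] = BetaClass.HIGH
    cls[power <= p_low] = BetaClass.LOW  # ties resolve to LOW
    out.loc[sel, "beta_class"] = cls
    return out
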