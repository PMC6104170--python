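"""Epoch-by-epoch EEG band-power stability statistic.

For every pair of consecutive epochs carrying the same effective state label
(AW, IW, QW, SWS or REMS — wake is paired at substate resolution), the change
in band power is expressed as a percentage of the first epoch's power in that
band:

    change = 100 × |P(i+1) − P(i)| / P(i)

The per-(state × band) distribution of these changes is summarized by its mean
and 90th percentile. The absolute-value convention makes both summaries
magnitude-like (a signed mean of a stationary series would hover near zero);
signed changes are available for sensitivity analysis. Pairs may overlap
((i, i+1) and (i+1, i+2) both count); pairs with a zero denominator are
excluded and tallied.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .recording import EFFECTIVE_STATES, Hypnogram
from .substate import percentile


def same_state_pairs(hyp: Hypnogram) -> dict[str, np.ndarray]:
    """Indices ``i`` of all consecutive pairs (i, i+1) with identical effective
    labels, per state. Pairs involving UNSCORED epochs are excluded."""
    eff = hyp.effective_labels()
    out: dict[str, np.ndarray] = {}
    same = eff[:-1] == eff[1:] if len(eff) > 1 else np.array([], dtype=bool)
    for state in EFFECTIVE_STATES:
        out[state] = np.flatnonzero(same & (eff[:-1] == state))
    return out


def pair_change_pct(p_first: float, p_second: float, signed: bool = False) -> float:
    """Power change across one epoch pair as % of the first epoch's band power."""
    if p_first <= 0:
        raise ValueError("first epoch's band power must be positive")
    delta = 100.0 * (p_second - p_first) / p_first
    return delta if signed else abs(delta)


def _pair_changes(powers: np.ndarray, first_idx: np.ndarray, signed: bool) -> tuple[np.ndarray, int]:
    p1 = powers[first_idx]
    p2 = powers[first_idx + 1]
    ok = p1 > 0
    changes = 100.0 * (p2[ok] - p1[ok]) / p1[ok]
    if not signed:
        changes = np.abs(changes)
    return changes, int((~ok).sum())


def stability_summary(
    table: pd.DataFrame,
    hyp: Hypnogram,
    bands: list[str] | None = None,
    signed: bool = False,
) -> pd.DataFrame:
    """Long-format summary: one row per state × band with the mean and 90th
    percentile of the normalized epoch-by-epoch change, and the pair count.

    States with zero pairs get ``n_pairs = 0`` and missing summary values.
    """
    if bands is None:
        bands = [c[len("power_"):] for c in table.columns if c.startswith("power_")]
    pairs = same_state_pairs(hyp)
    n = len(table)
    rows = []
    for state in EFFECTIVE_STATES:
        idx = pairs[state]
        idx = idx[idx + 1 < n]
        for band in bands:
            powers = table[f"power_{band}"].to_numpy(float)
            changes, n_excluded = _pair_changes(powers, idx, signed)
            rows.append({
                "state": state,
                "band": band,
                "mean_change_pct": float(np.mean(changes)) if len(changes) else np.nan,
                "p90_change_pct": percentile(changes, 90.0) if len(changes) else np.nan,
                "n_pairs": len(changes),
                "n_excluded": n_excluded,
            })
    return pd.DataFrame(rows)
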