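import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

import stabvep as sv


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(eeg=None, emg=None, ttl=None, n=4000, fs=400.0, **kwargs):
    """Recording with zero-filled channels where unspecified."""
    if eeg is not None:
        n = len(eeg)
    elif emg is not None:
        n = len(emg)
    zeros = np.zeros(n)
    return sv.Recording(
        eeg=zeros if eeg is None else eeg,
        emg=zeros if emg is None else emg,
        ttl=zeros if ttl is None else ttl,
        sample_rate_hz=fs,
        **kwargs,
    )


def make_features(base_labels, substates=None, emg_rms=None, beta=None, **powers):
    """Minimal per-epoch feature table for classifier/stability tests."""
    n = len(base_labels)
    table = pd.DataFrame({
        "epoch_index": np.arange(n),
        "base_label": np.asarray(base_labels, dtype="U8"),
        "wake_substate": (np.asarray(substates, dtype="U8") if substates is not None
                          else np.full(n, "NOT_WAKE", dtype="U8")),
        "beta_class": np.full(n, "UNASSIGNED", dtype="U10"),
        "interval_label": np.full(n, "H12", dtype="U4"),
        "emg_rms": np.zeros(n) if emg_rms is None else np.asarray(emg_rms, float),
    })
    if beta is not None:
        table["power_beta"] = np.asarray(beta, float)
    for name, values in powers.items():
        table[f"power_{name}"] = np.asarray(values, float)
    return table


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def features_factory():
    return make_features
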