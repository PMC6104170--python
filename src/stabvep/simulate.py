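"""Ground-truthed synthetic polysomnography generator.

Emulates the statistical structure the analysis assumes, so every pipeline
stage can be exercised without real recordings:

* a semi-Markov hypnogram over WAKE/SWS/REMS (geometric dwell times; REMS is
  entered only from SWS, the standard rodent architecture), with a persistent
  latent AW/IW/QW chain refining wake;
* state-dependent EEG built from narrowband oscillators (band-filtered noise,
  or a pure sinusoid when bandwidth is 0) plus broadband noise — delta-dominant
  SWS, theta-dominant REMS, low-amplitude wake;
* epoch-to-epoch lognormal amplitude jitter (larger in SWS, mimicking the
  waxing/waning of slow-wave packets) and intermittent beta-band surges in
  wake/REMS epochs with configurable rate and lognormal magnitude;
* sleep-need-dependent beta buildup in quiet wake (amplitude grows with prior
  time awake);
* state-dependent EMG tone (AW > IW > QW > SWS ≈ REMS) with lognormal jitter;
* a 1-Hz train of 10-ms TTL pulses, each adding a biphasic evoked-potential
  template (negative lobe peaking 150 ms, positive lobe 250 ms after onset)
  scaled by the effective state of the onset epoch. The template is normalized
  so that value(+250 ms) − value(+150 ms) equals the configured state scale.

A master seed is split into named substreams (hypnogram, substate, modulation,
oscillator, noise, emg) so each component is independently reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfilt

from .recording import (
    BaseState,
    Condition,
    Hypnogram,
    Recording,
    StimulusTrain,
    WakeSubstate,
)
from . import recording_io

_STREAMS = ("hypnogram", "substate", "modulation", "oscillator", "noise", "emg")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass(frozen=True)
class Oscillator:
    """Narrowband EEG component: center frequency (Hz), RMS amplitude (μV),
    bandwidth (Hz; 0 means a deterministic sinusoid)."""

    center_hz: float
    amplitude_uv: float
    bandwidth_hz: float = 1.0


def _default_oscillators() -> dict[str, list[Oscillator]]:
    return {
        "AW": [Oscillator(7.5, 30.0, 2.0), Oscillator(10.0, 12.0, 2.0),
               Oscillator(25.0, 12.0, 4.0), Oscillator(2.5, 8.0, 1.5)],
        "IW": [Oscillator(7.0, 22.0, 2.0), Oscillator(10.0, 14.0, 2.0),
               Oscillator(25.0, 13.0, 4.0), Oscillator(2.5, 10.0, 1.5)],
        "QW": [Oscillator(7.0, 15.0, 2.0), Oscillator(10.0, 15.0, 2.0),
               Oscillator(25.0, 14.0, 4.0), Oscillator(2.5, 12.0, 1.5)],
        "SWS": [Oscillator(2.5, 90.0, 1.5), Oscillator(6.0, 15.0, 2.0),
                Oscillator(11.0, 20.0, 2.0), Oscillator(25.0, 12.0, 4.0)],
        "REMS": [Oscillator(7.0, 55.0, 1.5), Oscillator(25.0, 14.0, 4.0),
                 Oscillator(2.5, 8.0, 1.5)],
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session (defaults: a 6-h, 400-Hz
    spontaneous-sleep session with 1-Hz photic stimulation)."""

    duration_h: float = 6.0
    sample_rate_hz: float = 400.0
    epoch_length_s: float = 10.0
    subject_id: str = "sim"
    condition: str = "SPONTANEOUS"
    session_start_zt_h: float = 2.0
    sd_hours: float = 4.0            # forced-wake span on a sleep-disruption day

    mean_dwell_epochs: dict = field(default_factory=lambda: {"WAKE": 10.0, "SWS": 12.0, "REMS": 5.0})
    transitions: dict = field(default_factory=lambda: {
        "WAKE": {"SWS": 1.0},
        "SWS": {"WAKE": 0.7, "REMS": 0.3},
        "REMS": {"WAKE": 0.8, "SWS": 0.2},
    })
    substate_self_stay: float = 0.6

    oscillators: dict = field(default_factory=_default_oscillators)
    noise_sd_uv: float = 15.0
    amp_jitter_sigma: dict = field(default_factory=lambda: {
        "AW": 0.08, "IW": 0.08, "QW": 0.08, "SWS": 0.35, "REMS": 0.08,
    })

    emg_rms_uv: dict = field(default_factory=lambda: {
        "AW": 40.0, "IW": 18.0, "QW": 8.0, "SWS": 4.0, "REMS": 3.0,
    })
    emg_jitter_sigma: float = 0.2

    surge_rate: float = 0.02             # probability a wake/REMS epoch carries a surge
    surge_magnitude_mean: float = 2.0    # median amplitude multiplier of the beta oscillator
    surge_magnitude_sigma: float = 0.4   # lognormal spread of the multiplier
    beta_buildup_per_h: float = 0.10     # fractional QW beta-amplitude rise per hour awake
    beta_low_hz: float = 15.0
    beta_high_hz: float = 35.0

    vep_scale_uv: dict = field(default_factory=lambda: {
        "SWS": 100.0, "QW": 95.0, "IW": 75.0, "REMS": 72.0, "AW": 70.0,
    })
    stimulus_rate_hz: float = 1.0        # 0 disables stimulation
    pulse_duration_s: float = 0.010
    crossfade_s: float = 0.2

    def __post_init__(self) -> None:
        self.condition = str(Condition(self.condition))
        osc = {}
        for state, items in self.oscillators.items():
            osc[state] = [o if isinstance(o, Oscillator) else Oscillator(*o) for o in items]
        self.oscillators = osc
        for state, row in self.transitions.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition row {state} sums to {total}, not 1")
        if self.transitions.get("WAKE", {}).get("REMS", 0.0) > 0:
            raise ValueError("REMS may not follow WAKE directly")

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.epoch_length_s))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["oscillators"] = {
            s: [[o.center_hz, o.amplitude_uv, o.bandwidth_hz] for o in items]
            for s, items in self.oscillators.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


PRESETS: dict[str, dict] = {
    # rare, modest beta surges: baseline-like EEG dynamics
    "wildtype_like": {},
    # frequent, larger and more variable surges: the instability phenotype
    "mutant_like": {"surge_rate": 0.16, "surge_magnitude_mean": 2.2,
                    "surge_magnitude_sigma": 0.6},
    "sd_day": {"condition": "SLEEP_DISRUPTION"},
    "spontaneous_day": {"condition": "SPONTANEOUS"},
}


def preset_config(name: str, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """Latent variables of one generated session, aligned with the epoch grid
    and the stimulus train."""

    effective_labels: np.ndarray
    surge_multiplier: np.ndarray    # amplitude multiplier; 1.0 outside surge epochs
    true_emg_rms: np.ndarray
    qw_beta_gain: np.ndarray        # sleep-need buildup factor applied in QW
    trial_onset_s: np.ndarray
    trial_state: np.ndarray
    trial_amplitude_uv: np.ndarray


def epoch_transition_matrix(cfg: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Equivalent per-epoch Markov matrix of the semi-Markov chain (geometric
    dwells are memoryless): stay with 1 − 1/dwell, else jump per the embedded
    transition row."""
    states = ["WAKE", "SWS", "REMS"]
    P = np.zeros((3, 3))
    for i, s in enumerate(states):
        leave = 1.0 / cfg.mean_dwell_epochs[s]
        P[i, i] = 1.0 - leave
        for t, p in cfg.transitions.get(s, {}).items():
            P[i, states.index(t)] += leave * p
    return states, P


def generate_hypnogram(cfg: SimulationConfig, seed: int) -> Hypnogram:
    """Semi-Markov base labels plus latent wake substates; deterministic under
    a fixed seed. On a sleep-disruption day the first ``sd_hours`` are forced
    to WAKE."""
    rngs = _rngs(seed)
    rng = rngs["hypnogram"]
    n = cfg.n_epochs
    labels = np.empty(n, dtype="U8")
    state = "WAKE"
    i = 0
    while i < n:
        dwell = rng.geometric(1.0 / cfg.mean_dwell_epochs[state])
        labels[i : i + dwell] = state
        i += dwell
        row = cfg.transitions[state]
        nxt = list(row)
        state = nxt[rng.choice(len(nxt), p=np.array([row[k] for k in nxt]))]
    if Condition(cfg.condition) is Condition.SLEEP_DISRUPTION:
        sd_epochs = int(round(cfg.sd_hours * 3600.0 / cfg.epoch_length_s))
        labels[:sd_epochs] = "WAKE"

    rng_sub = rngs["substate"]
    subs = ("AW", "IW", "QW")
    stay = cfg.substate_self_stay
    chain = np.empty(n, dtype=int)
    chain[0] = rng_sub.choice(3)
    for k in range(1, n):
        if rng_sub.random() < stay:
            chain[k] = chain[k - 1]
        else:  # move to one of the two other substates, equiprobably
            chain[k] = (chain[k - 1] + 1 + int(rng_sub.random() < 0.5)) % 3
    substates = np.full(n, WakeSubstate.NOT_WAKE, dtype="U8")
    wake = labels == "WAKE"
    substates[wake] = np.array(subs, dtype="U8")[chain[wake]]
    return Hypnogram(labels, epoch_length_s=cfg.epoch_length_s, wake_substates=substates)


def vep_template(sample_rate_hz: float, length_s: float = 0.5) -> np.ndarray:
    """Biphasic evoked-potential template on [0, length_s]: negative Gaussian
    lobe peaking at 150 ms, broader positive lobe at 250 ms; normalized so
    value(+250 ms) − value(+150 ms) = 1 at the sampled grid points."""
    t = np.arange(int(round(length_s * sample_rate_hz)) + 1) / sample_rate_hz
    v = -np.exp(-0.5 * ((t - 0.150) / 0.030) ** 2) \
        + 0.5 * np.exp(-0.5 * ((t - 0.250) / 0.060) ** 2)
    i_neg = int(round(0.150 * sample_rate_hz))
    i_pos = int(round(0.250 * sample_rate_hz))
    return v / (v[i_pos] - v[i_neg])


def _is_beta(osc: Oscillator, cfg: SimulationConfig) -> bool:
    return cfg.beta_low_hz <= osc.center_hz <= cfg.beta_high_hz


def generate_signals(
    hyp: Hypnogram, cfg: SimulationConfig, seed: int
) -> tuple[Recording, GroundTruth]:
    """Render EEG/EMG/TTL for a hypnogram (substates must be filled).

    The same master seed used for :func:`generate_hypnogram` may be reused
    here: the two functions draw from disjoint named substreams.
    """
    if hyp.wake_substates is None and (hyp.base_labels == BaseState.WAKE).any():
        raise ValueError("hypnogram must carry wake substates before signal synthesis")
    rngs = _rngs(seed)
    fs = cfg.sample_rate_hz
    spe = int(round(fs * hyp.epoch_length_s))
    n_epochs = hyp.n_epochs
    n = n_epochs * spe
    eff = hyp.effective_labels()
    smooth = max(1, int(round(cfg.crossfade_s * fs)))

    # --- per-epoch modulation (modulation stream) ---
    rng_mod = rngs["modulation"]
    keys = sorted({(o.center_hz, o.bandwidth_hz)
                   for items in cfg.oscillators.values() for o in items})
    sigma = np.array([cfg.amp_jitter_sigma.get(s, 0.0) for s in eff])
    jitter = {}
    for key in keys:
        z = rng_mod.standard_normal(n_epochs)
        jitter[key] = np.exp(sigma * z - 0.5 * sigma**2)  # mean-one lognormal

    eligible = np.isin(eff, ("AW", "IW", "QW", "REMS"))
    surge_hit = (rng_mod.random(n_epochs) < cfg.surge_rate) & eligible
    z = rng_mod.standard_normal(n_epochs)
    surge_mult = np.ones(n_epochs)
    surge_mult[surge_hit] = np.exp(
        math.log(cfg.surge_magnitude_mean) + cfg.surge_magnitude_sigma * z[surge_hit]
    )

    wake_epochs = (hyp.base_labels == BaseState.WAKE).astype(float)
    hours_awake = (np.cumsum(wake_epochs) - wake_epochs) * hyp.epoch_length_s / 3600.0
    qw_gain = np.where(eff == "QW", 1.0 + cfg.beta_buildup_per_h * hours_awake, 1.0)

    # --- EEG: oscillators + white noise (oscillator & noise streams) ---
    rng_osc = rngs["oscillator"]
    eeg = np.zeros(n)
    amp_of = {
        key: {s: next((o.amplitude_uv for o in items if (o.center_hz, o.bandwidth_hz) == key), 0.0)
              for s, items in cfg.oscillators.items()}
        for key in keys
    }
    t = np.arange(n) / fs
    for key in keys:
        center, bw = key
        amp = np.array([amp_of[key].get(s, 0.0) for s in eff]) * jitter[key]
        if cfg.beta_low_hz <= center <= cfg.beta_high_hz:
            amp = amp * surge_mult * qw_gain
        if not amp.any():
            continue
        envelope = uniform_filter1d(np.repeat(amp, spe), size=smooth, mode="nearest")
        if bw <= 0:
            component = math.sqrt(2.0) * np.sin(2.0 * np.pi * center * t)
        else:
            sos = butter(2, [center - bw / 2.0, center + bw / 2.0],
                         btype="bandpass", fs=fs, output="sos")
            component = sosfilt(sos, rng_osc.standard_normal(n))
            component /= component.std()
        eeg += envelope * component
    if cfg.noise_sd_uv > 0:
        eeg += cfg.noise_sd_uv * rngs["noise"].standard_normal(n)

    # --- EMG (emg stream) ---
    rng_emg = rngs["emg"]
    base_rms = np.array([cfg.emg_rms_uv.get(s, 0.0) for s in eff])
    s_emg = cfg.emg_jitter_sigma
    true_rms = base_rms * np.exp(s_emg * rng_emg.standard_normal(n_epochs) - 0.5 * s_emg**2)
    emg = rng_emg.standard_normal(n) * uniform_filter1d(
        np.repeat(true_rms, spe), size=smooth, mode="nearest"
    )

    # --- stimulation: TTL pulses + evoked templates ---
    ttl = np.zeros(n)
    trial_onset_s = np.array([])
    trial_state = np.array([], dtype="U8")
    trial_amp = np.array([])
    if cfg.stimulus_rate_hz > 0:
        step = 1.0 / cfg.stimulus_rate_hz
        onset_samples = np.rint(
            np.arange(0.0, n / fs - 1e-9, step) * fs
        ).astype(int)
        onset_samples = onset_samples[onset_samples < n]
        pulse = max(1, int(round(cfg.pulse_duration_s * fs)))
        template = vep_template(fs)
        states = eff[np.minimum(onset_samples // spe, n_epochs - 1)]
        amps = np.array([cfg.vep_scale_uv.get(s, 0.0) for s in states])
        for onset, amp in zip(onset_samples, amps):
            ttl[onset : onset + pulse] = 1.0
            stop = min(n, onset + len(template))
            eeg[onset:stop] += amp * template[: stop - onset]
        trial_onset_s = onset_samples / fs
        trial_state = states
        trial_amp = amps

    rec = Recording(
        eeg=eeg, emg=emg, ttl=ttl, sample_rate_hz=fs,
        session_start_zt_h=cfg.session_start_zt_h,
        subject_id=cfg.subject_id, condition=Condition(cfg.condition),
    )
    truth = GroundTruth(
        effective_labels=eff,
        surge_multiplier=surge_mult,
        true_emg_rms=true_rms,
        qw_beta_gain=qw_gain,
        trial_onset_s=trial_onset_s,
        trial_state=trial_state,
        trial_amplitude_uv=trial_amp,
    )
    return rec, truth


def generate_session(
    cfg: SimulationConfig,
    out_dir,
    seed: int,
    dialect: str = "EDF",
) -> dict[str, Path]:
    """Generate and write a complete fixture set: recording, hypnogram, ground
    truth tables and the resolved configuration. Byte-identical under a fixed
    seed."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hyp = generate_hypnogram(cfg, seed)
    rec, truth = generate_signals(hyp, cfg, seed)

    ext = "edf" if dialect.upper() == "EDF" else "csv"
    paths = {
        "recording": out / f"recording.{ext}",
        "hypnogram": out / "hypnogram.csv",
        "ground_truth_epochs": out / "ground_truth_epochs.csv",
        "ground_truth_trials": out / "ground_truth_trials.csv",
        "config": out / "sim_config.yaml",
    }
    recording_io.write_recording(rec, paths["recording"], dialect=dialect)
    recording_io.write_hypnogram(hyp, paths["hypnogram"])
    pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "effective_state": truth.effective_labels,
        "surge_multiplier": truth.surge_multiplier,
        "true_emg_rms": truth.true_emg_rms,
        "qw_beta_gain": truth.qw_beta_gain,
    }).to_csv(paths["ground_truth_epochs"], index=False)
    pd.DataFrame({
        "trial_index": np.arange(len(truth.trial_onset_s)),
        "onset_s": truth.trial_onset_s,
        "state": truth.trial_state,
        "amplitude_uv": truth.trial_amplitude_uv,
    }).to_csv(paths["ground_truth_trials"], index=False)
    resolved = cfg.to_dict()
    resolved["seed"] = seed
    Path(paths["config"]).write_text(yaml.safe_dump(resolved, sort_keys=True))
    return paths
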