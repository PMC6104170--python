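"""Per-epoch EMG root-mean-square and EEG band power.

Band power for a 10-s epoch is computed by splitting the epoch into five
contiguous 2-s segments, taking a Hann-tapered discrete Fourier power spectrum
of each (per-segment mean removed), averaging the five spectra bin-wise, and
summing averaged bin power over the band. Normalization is Parseval-consistent
and amplitude-faithful: the one-sided bin powers of a sinusoid of amplitude A
sum to A²/2 μV², and the bin powers over (0, Nyquist] sum to the tapered
signal's mean square. At 400 Hz the 2-s segments give 0.5-Hz bins; bands are
closed on both edges and the DC bin is always excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .errors import BandConfigError
from .recording import BaseState, BetaClass, Hypnogram, Recording, WakeSubstate

SEGMENTS_PER_EPOCH = 5

#: standard bands: delta, theta, alpha, beta (Hz)
@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def validate(self, sample_rate_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz < sample_rate_hz / 2:
            raise BandConfigError(
                f"band {self.name}: need 0 < low < high < Nyquist "
                f"({self.low_hz}, {self.high_hz}, fs={sample_rate_hz})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 5.0, 8.0),
    BandDefinition("alpha", 9.0, 12.0),
    BandDefinition("beta", 15.0, 35.0),
)

#: wider alpha variant (8–12 Hz) selectable through configuration
ALPHA_WIDE = BandDefinition("alpha", 8.0, 12.0)


def _epoch_matrix(x: np.ndarray, hyp: Hypnogram, fs: float) -> tuple[np.ndarray, int]:
    """Trim ``x`` to whole epochs covered by both signal and hypnogram and
    reshape to (n_epochs, samples_per_epoch)."""
    spe = int(round(fs * hyp.epoch_length_s))
    n_epochs = min(hyp.n_epochs, len(x) // spe)
    return x[: n_epochs * spe].reshape(n_epochs, spe), n_epochs


def epoch_emg_rms(rec: Recording, hyp: Hypnogram) -> np.ndarray:
    """RMS of the EMG within each epoch's window (μV); one value per epoch
    fully covered by the recording."""
    mat, _ = _epoch_matrix(rec.emg, hyp, rec.sample_rate_hz)
    return np.sqrt(np.mean(mat * mat, axis=1))


def segment_power_spectrum(segments: np.ndarray, sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-tapered power spectrum of each row of ``segments``.

    Returns ``(freqs, power)`` where ``power[..., k]`` sums to the mean square
    of the (mean-removed) signal; a sinusoid of amplitude A contributes A²/2.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    n = segments.shape[-1]
    w = hann(n, sym=False)
    x = segments - segments.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x * w, axis=-1)
    power = (spec.real**2 + spec.imag**2) / (n * np.sum(w * w))
    power[..., 1:] *= 2.0
    if n % 2 == 0:
        power[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    return freqs, power


def _band_mask(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    tol = 1e-9
    mask = (freqs >= band.low_hz - tol) & (freqs <= band.high_hz + tol)
    mask[0] = False  # DC always excluded
    return mask


def epoch_band_power(
    rec: Recording,
    hyp: Hypnogram,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-epoch band power (μV²), one column per band.

    Each epoch is split into five equal contiguous segments whose Hann-tapered
    spectra are averaged bin-wise before summing over band bins.
    """
    fs = rec.sample_rate_hz
    for b in bands:
        b.validate(fs)
    mat, n_epochs = _epoch_matrix(rec.eeg, hyp, fs)
    spe = mat.shape[1]
    if spe % SEGMENTS_PER_EPOCH:
        raise BandConfigError(
            f"epoch of {spe} samples does not divide into {SEGMENTS_PER_EPOCH} segments"
        )
    nper = spe // SEGMENTS_PER_EPOCH
    freqs, power = segment_power_spectrum(mat.reshape(n_epochs, SEGMENTS_PER_EPOCH, nper), fs)
    avg = power.mean(axis=1)  # bin-wise mean of the five segment spectra
    out = {}
    for b in bands:
        mask = _band_mask(freqs, b)
        if not mask.any():
            raise BandConfigError(f"band {b.name} ({b.low_hz}-{b.high_hz} Hz) contains no bins")
        out[b.name] = avg[:, mask].sum(axis=1)
    return pd.DataFrame(out)


def broadband_power(rec: Recording, hyp: Hypnogram, low_hz: float, high_hz: float) -> np.ndarray:
    """Per-epoch power summed over an ad-hoc band — same machinery as
    :func:`epoch_band_power` with a single band."""
    name = f"{low_hz:g}-{high_hz:g}Hz"
    return epoch_band_power(rec, hyp, (BandDefinition(name, low_hz, high_hz),))[name].to_numpy()


def interval_labels(hyp: Hypnogram, n_epochs: int) -> np.ndarray:
    """2-h analysis interval of each epoch (by epoch start): H12 for the first
    two hours of the session, H34 for hours 3–4, H56 for hours 5–6, NONE after."""
    starts = np.arange(n_epochs) * hyp.epoch_length_s
    labels = np.full(n_epochs, "NONE", dtype="U4")
    labels[starts < 6 * 3600] = "H56"
    labels[starts < 4 * 3600] = "H34"
    labels[starts < 2 * 3600] = "H12"
    return labels


def build_epoch_features(
    rec: Recording,
    hyp: Hypnogram,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Assemble the per-epoch feature table: labels, EMG RMS, band powers and
    2-h interval label. Band power columns are named ``power_<band>``."""
    power = epoch_band_power(rec, hyp, bands)
    n = len(power)
    substates = (
        hyp.wake_substates[:n]
        if hyp.wake_substates is not None
        else np.where(hyp.base_labels[:n] == BaseState.WAKE, "", WakeSubstate.NOT_WAKE)
    )
    beta_cls = (
        hyp.beta_classes[:n]
        if hyp.beta_classes is not None
        else np.full(n, BetaClass.UNASSIGNED, dtype="U10")
    )
    table = pd.DataFrame({
        "epoch_index": np.arange(n),
        "base_label": hyp.base_labels[:n],
        "wake_substate": substates,
        "beta_class": beta_cls,
        "interval_label": interval_labels(hyp, n),
        "emg_rms": epoch_emg_rms(rec, hyp),
    })
    for name in power.columns:
        table[f"power_{name}"] = power[name].to_numpy()
    return table
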