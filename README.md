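# stabvep

State-dependent EEG band-power stability and visual evoked potential (VEP)
analysis for rodent polysomnography.

Sleep-neurophysiology experiments that pair chronic EEG/EMG recording with
photic stimulation ask two recurring questions: how *stable* is cortical
network activity within a vigilance state from one scoring epoch to the next,
and how does the cortical response to a sensory stimulus change with vigilance
state and with accumulated sleep need? `stabvep` implements this analysis as a
tested, reusable pipeline: epoch-wise spectral band power, EMG-based wake
substate classification, an epoch-by-epoch band-power instability statistic,
beta-percentile stratification, and state-sorted VEP extraction and scoring —
plus a ground-truthed synthetic polysomnography generator so the whole
pipeline can be exercised and validated without any recordings.

## The analysis

Inputs are synchronized EEG, EMG and a binary TTL stimulus trace (μV, common
sampling rate, 400 Hz default) with a 10-s-epoch hypnogram over WAKE / SWS
(slow wave sleep) / REMS (rapid eye movement sleep).

**Band power.** Each 10-s epoch is split into five 2-s segments; each segment
gets a Hann-tapered FFT power spectrum (0.5-Hz bins, DC removed), the five
spectra are averaged bin-wise, and power is summed over delta (1–4 Hz), theta
(5–8), alpha (9–12) and beta (15–35). Normalization is amplitude-faithful: a
sinusoid of amplitude *A* contributes *A²/2* μV² to its band.

**Wake substates.** With *r*ᵢ the EMG RMS of wake epoch *i* and *p₃₃*, *p₆₆*
the 33rd/66th percentiles of {*r*ᵢ} over all wake epochs of the recording:
quiet wakefulness (QW) if *r*ᵢ ≤ *p₃₃*, active wakefulness (AW) if
*r*ᵢ ≥ *p₆₆*, intermediate (IW) otherwise.

**Instability statistic.** For every pair of consecutive epochs with the same
effective state *s* ∈ {AW, IW, QW, SWS, REMS} and band power *P*:

    Δ = 100 · |P(i+1) − P(i)| / P(i)   (%)

summarized per state × band by the mean and the 90th percentile of Δ.
Transient power surges — the instability phenotype — load on the 90th
percentile without moving the modal power.

**VEPs.** Every 10-ms light pulse contributes the EEG from 0.5 s before to
0.5 s after onset; trials are sorted by the effective state at onset
(optionally crossed with the epoch's beta class, ≤p20 / ≥p80 within state, and
2-h session interval) and averaged point-wise. Magnitude is
*V*(+250 ms) − *V*(+150 ms) of the average waveform — the positive lobe minus
the negative lobe, read at exact grid samples at 400 Hz.

## Worked example

```python
import stabvep as sv

cfg = sv.SimulationConfig(duration_h=2.0)        # 2-h synthetic session
hyp = sv.generate_hypnogram(cfg, seed=3)
rec, truth = sv.generate_signals(hyp, cfg, seed=3)
train = sv.extract_stimulus_train(rec)
print(sv.vep_table(rec, train, hyp, group_by=("state",), min_trials=10))
```

prints

```
state  magnitude_uv  n_trials
   AW          70.6       770
   IW          79.0       890
   QW          96.7       829
 REMS          72.4       510
  SWS          97.3      4200
```

i.e. the state-sorted VEP magnitudes recover the generator's injected template
scales (AW 70, IW 75, QW 95, REMS 72, SWS 100 μV) to within trial noise, and
reproduce the characteristic partial order SWS ≈ QW > IW ≈ REMS ≈ AW: evoked
responses are large in slow wave sleep and quiet wake, small in aroused
states. See `examples/` for one short script per capability (simulation,
band power + substates, the instability statistic, VEPs, and the shell
workflow via the `stabvep` CLI: `simulate` / `analyze` / `report` /
`show-config`).

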