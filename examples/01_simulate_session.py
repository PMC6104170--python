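"""Generate a short synthetic polysomnography session and inspect it.

The generator produces a semi-Markov WAKE/SWS/REMS hypnogram with latent
AW/IW/QW wake substates, state-dependent EEG/EMG, a 1-Hz train of 10-ms light
pulses, and the ground truth needed to verify every later analysis stage.
"""
import collections

import stabvep as sv

cfg = sv.SimulationConfig(duration_h=1.0)  # 360 ten-second epochs at 400 Hz
hyp = sv.generate_hypnogram(cfg, seed=1)
rec, truth = sv.generate_signals(hyp, cfg, seed=1)

print("samples per channel:", rec.n_samples, f"({rec.duration_s:.0f} s at {rec.sample_rate_hz:g} Hz)")
print("epoch composition:  ", dict(collections.Counter(map(str, truth.effective_labels))))
print("stimuli delivered:  ", len(truth.trial_onset_s))
print("surge epochs:       ", int((truth.surge_multiplier > 1).sum()),
      "(beta-band power surges injected into wake/REMS epochs)")

# Epoch counts show rodent-like architecture (wake-dominant early session);
# each stimulus carries an evoked template scaled by the state it fell in.
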