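amp_jitter_sigma:
  AW: 0.08
  IW: 0.08
  QW: 0.08
  REMS: 0.08
  SWS: 0.35
beta_buildup_per_h: 0.1
beta_high_hz: 35.0
beta_low_hz: 15.0
condition: SPONTANEOUS
crossfade_s: 0.2
duration_h: 0.5
emg_jitter_sigma: 0.2
emg_rms_uv:
  AW: 40.0
  IW: 18.0
  QW: 8.0
  REMS: 3.0
  SWS: 4.0
epoch_length_s: 10.0
mean_dwell_epochs:
  REMS: 5.0
  SWS: 12.0
  WAKE: 10.0
noise_sd_uv: 15.0
oscillators:
  AW:
  - - 7.5
    - 30.0
    - 2.0
  - - 10.0
    - 12.0
    - 2.0
  - - 25.0
    - 12.0
    - 4.0
  - - 2.5
    - 8.0
    - 1.5
  IW:
  - - 7.0
    - 22.0
    - 2.0
  - - 10.0
    - 14.0
    - 2.0
  - - 25.0
    - 13.0
    - 4.0
  - - 2.5
    - 10.0
    - 1.5
  QW:
  - - 7.0
    - 15.0
    - 2.0
  - - 10.0
    - 15.0
    - 2.0
  - - 25.0
    - 14.0
    - 4.0
  - - 2.5
    - 12.0
    - 1.5
  REMS:
  - - 7.0
    - 55.0
    - 1.5
  - - 25.0
    - 14.0
    - 4.0
  - - 2.5
    - 8.0
    - 1.5
  SWS:
  - - 2.5
    - 90.0
    - 1.5
  - - 6.0
    - 15.0
    - 2.0
  - - 11.0
    - 20.0
    - 2.0
  - - 25.0
    - 12.0
    - 4.0
pulse_duration_s: 0.01
sample_rate_hz: 400.0
sd_hours: 4.0
session_start_zt_h: 2.0
stimulus_rate_hz: 1.0
subject_id: sim
substate_self_stay: 0.6
surge_magnitude_mean: 2.0
surge_magnitude_sigma: 0.4
surge_rate: 0.02
transitions:
  REMS:
    SWS: 0.2
    WAKE: 0.8
  SWS:
    REMS: 0.3
    WAKE: 0.7
  WAKE:
    SWS: 1.0
vep_scale_uv:
  AW: 70.0
  IW: 75.0
  QW: 95.0
  REMS: 72.0
  SWS: 100.0
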