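# Methods

This note documents the models, conventions and design choices behind
`stabvep`: what each stage computes, what the synthetic generator does and
does not emulate, and where the genuinely open choices were made.

## Time and epoch conventions

Sample `i` occupies `[i/fs, (i+1)/fs)`; all times are seconds from recording
start with 0-based indices. Epochs are half-open `[10k, 10(k+1))` s (length
configurable), so an event exactly on a boundary belongs to the later epoch.
A recording's epoch grid is `floor(duration / epoch_length)`; a trailing
partial epoch is never scored.

## Spectral estimation

Per-epoch band power uses five contiguous, non-overlapping 2-s segments per
10-s epoch. Each segment is mean-removed, Hann-tapered (periodic window), and
transformed with an FFT; the five one-sided power spectra are averaged
bin-wise before summing over band bins. At 400 Hz this gives 0.5-Hz bins.

Normalization is Parseval-consistent: bin power is
`2|X_k|² / (N · Σw²)` (one-sided, halved at DC/Nyquist), so the bins of a
sinusoid of amplitude A sum to A²/2 and the non-DC bins sum to the tapered
signal's mean square. This keeps band power in physical μV² and makes band
sums exactly additive over disjoint bands — both properties are tested.

Bands are closed on both edges on the bin grid (delta 1–4, theta 5–8, alpha
9–12, beta 15–35 Hz); the gaps between printed band edges (4→5, 8→9, 12→15)
are respected, not bridged, and the DC bin is always excluded. An 8–12 Hz
alpha variant (`ALPHA_WIDE`) is available where the wider convention is
wanted; 9–12 Hz is the default. No detrending is applied beyond per-segment
mean removal, and no multitaper/wavelet options are offered: the instability
statistic below is a ratio of like-computed powers, so the estimator's bias
cancels.

## Wake substates and beta stratification

Percentiles throughout the package use linear interpolation between order
statistics (quantile *q* at position `1 + (n−1)q`, NumPy's `method="linear"`).
The convention is pinned so results are bit-reproducible; it also matches the
common spreadsheet/statistics default. Percentile populations are always
*per recording* — never pooled across sessions or animals — and, for beta
stratification, per effective state within the recording. On a 6-h session
with stimulation this means per-session (not per-2-h-interval) thresholds.

Degenerate ties: an epoch satisfying both the low and high conditions
(possible only under massive ties) takes the low class (QW, resp. LOW). This
is deterministic, documented, and exercised by tests.

Note that the ≥p66 rule assigns ≈0.34·n epochs to AW (not exactly a third),
so tertile-count balance checks hold to ±2 epochs only for recordings up to
≈200 wake epochs; the classifier itself is defined for any n ≥ 3.

## Instability statistic

Only consecutive epoch pairs with identical *effective* labels count, where
wake is resolved at substate resolution (QW–QW, IW–IW, AW–AW) since the
desynchronized states are reported separately. Pairs may overlap; pairs whose
first epoch has zero band power are excluded and tallied; pairs spanning 2-h
interval boundaries are included.

The change is `100·|P₂−P₁|/P₁`. The absolute-value convention was chosen
because both summaries (mean, p90) are magnitude-like quantities: a signed
mean of a stationary series hovers near zero and carries no instability
information. A `signed=True` flag exposes the signed variant for sensitivity
analysis.

## VEP extraction and scoring

Windows cover onset −0.5 s … +0.5 s inclusive (401 samples at 400 Hz, onset
at the center sample); windows crossing a recording boundary are dropped and
tallied. Trials are labeled by the epoch containing the onset sample only —
no exclusion of trials whose window spans a state transition, since onset
state is what gates the evoked response. Averages are arithmetic means (not
sums), so magnitudes are comparable across groups of unequal trial counts;
groups under `min_trials` (default 10) are omitted, never padded.

Magnitude is read at the nearest grid samples to +150 ms and +250 ms (exact
samples at 400 Hz). A ±12.5 ms local-extremum search is available as a
sensitivity variant but is off by default: fixed latencies are the standard
definition for mouse VEPs. No baseline correction is applied — the magnitude
is a within-waveform difference and is offset-invariant; pre-stimulus-mean
subtraction exists as a display option.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
defaults chosen to be rodent-typical:

* **Hypnogram** — semi-Markov chain over WAKE/SWS/REMS with geometric dwell
  times (means 10/12/5 epochs) and embedded transitions WAKE→SWS,
  SWS→{WAKE 0.7, REMS 0.3}, REMS→{WAKE 0.8, SWS 0.2}. REMS is reachable only
  from SWS (standard rodent architecture). Wake substates follow a persistent
  three-state chain (self-stay 0.6). A sleep-disruption day forces WAKE for
  the first 4 h.
* **EEG** — a per-state mix of narrowband oscillators realized as
  band-filtered white noise (2nd-order Butterworth, unit-RMS normalized)
  scaled by a per-epoch amplitude envelope, plus broadband white noise
  (15 μV). Bandwidth 0 degenerates to a pure sinusoid, giving a fully
  deterministic signal for exactness tests. Envelopes cross-fade over 0.2 s
  at epoch boundaries. SWS is delta-dominant (90 μV at 2.5 Hz), REMS
  theta-dominant (55 μV at 7 Hz), wake low-amplitude mixed.
* **Epoch-to-epoch variability** — lognormal amplitude jitter per oscillator
  per epoch, σ = 0.08 in desynchronized states and 0.35 in SWS. The large SWS
  value emulates the waxing/waning of slow-wave packets and spindle episodes
  and is what makes SWS the *least* stable state in the beta band under the
  rare-surge default — the qualitative contrast the instability statistic is
  designed to detect.
* **Beta surges** — each wake/REMS epoch independently carries a surge with
  probability `surge_rate` (default 0.02; the rate must sit well below 0.10
  for the 90th-percentile statistic in desynchronized states to reflect
  baseline variability rather than surges). A surge multiplies the beta
  oscillator amplitude by a lognormal factor (median 2.0, σ 0.4). The
  `mutant_like` preset sets rate 0.16, median 2.2, σ 0.6; the "genotype" is
  thus expressed as explicit surge parameters rather than a single coupled
  scalar, because multiplying a lognormal σ also shifts quantiles in ways a
  single "spread × k" knob cannot express cleanly.
* **Sleep-need buildup** — QW beta amplitude grows by 10 %/h of prior
  accumulated wake. With a 4-h forced-wake day this yields a quiet-wake beta
  *power* elevation of roughly a third in hours 3–4 relative to a spontaneous
  day — the magnitude such protocols report.
* **EMG** — white noise at per-state RMS (AW 40, IW 18, QW 8, SWS 4, REMS 3
  μV) with lognormal jitter σ 0.2, giving well-separated substates that an
  EMG-percentile classifier recovers at ≈95 %.
* **Stimulation** — 10-ms TTL pulses at 1 Hz from t = 0. Each pulse adds a
  biphasic template (negative Gaussian lobe peaking at 150 ms, width 30 ms;
  positive lobe at 250 ms, width 60 ms) normalized so that
  value(+250 ms) − value(+150 ms) = 1 at the sampled grid, then scaled by the
  onset epoch's state: SWS 100, QW 95, IW 75, REMS 72, AW 70 μV. The scales
  encode the partial order SWS ≈ QW > IW ≈ REMS ≈ AW with a QW/AW ratio of
  1.36, consistent with reported quiet-over-active elevations of a third to a
  half.
* **Seeding** — one master seed is split into named `SeedSequence` substreams
  (hypnogram, substate, modulation, oscillator, noise, emg), so e.g. the same
  hypnogram can be re-rendered with different noise, and
  `generate_hypnogram`/`generate_signals` may share a master seed without
  stream collisions. All outputs are byte-identical under a fixed seed.

**What the generator does not emulate.** No biophysical (thalamocortical)
modeling; no circadian modulation beyond the forced-wake schedule; no
artifacts, electrode drift or movement contamination; oscillator centers are
stationary within a state; and injected VEP amplitude depends on state only —
it is *not* coupled to the epoch's beta class, so the beta-stratified VEP
table shows no high-vs-low effect on synthetic data. Passing tests therefore
demonstrate that the pipeline recovers what the generator injects under
realistic noise, not that real recordings satisfy these models.

## File formats and numerics

EDF I/O is implemented in-package (fixed-layout ASCII header + little-endian
int16 records). The digital range is mapped symmetrically (−32767…32767) so
physical zero round-trips exactly; with the default ±2000 μV physical range
the quantization error is ≤ 0.031 μV. Sessions whose length is not a whole
number of 1-s records are zero-padded on disk with the true sample count
recorded in the header's reserved field and trimmed on read. Delimited-text
signal tables infer the rate from the median time spacing and reject relative
jitter above 1e-6. An independent reader (MNE) is used in the test suite to
cross-check files we write.

Analysis outputs are delimited tables with stable column order plus a JSON
manifest (config hash, input checksums, exclusion counts); reruns on
identical inputs are byte-identical, which the tests assert at full session
scale.

## Problem sizes used in validation

The validation suite runs entirely on synthetic data: oracle comparisons use
single epochs or 20-segment batches; parameter-recovery checks use 20 seeds
with ≈1050 trials per state (state-sorted VEPs) and 20 matched seeds × 3
surge-rate levels on a 480-epoch designed hypnogram (instability); the
end-to-end determinism check simulates and analyzes a full 6-h session
(8.64 M samples/channel, 21,600 stimuli) twice. The acceptance script uses
full 6-h spontaneous and sleep-disruption days and a 2-h preset comparison.

## Known limitations

* Automated WAKE/SWS/REMS staging is out of scope; base labels come from the
  scorer (or the generator's ground truth).
* Inferential statistics (ANOVA families, post-hoc tests) are out of scope;
  the pipeline produces the per-session metric tables such tests consume.
* The percentile convention and the absolute-change convention are pinned
  choices; both have config-level alternatives (`signed=True`,
  `ALPHA_WIDE`) but results are only comparable within one convention.
* EDF support covers the plain continuous profile used here (equal rates,
  one data block layout), not EDF+ annotations or discontinuous files.
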