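# Methods

## Audification model

The sonifier performs a deliberately minimal transformation: the raw
samples of one EEG channel of one 30-s epoch are reinterpreted at an
accelerated playback rate, with no feature extraction, pitch mapping or
musical rendering. Musical/mapping schemes risk making task-irrelevant
features salient; playing the data itself preserves whatever information
the waveform carries and lets the auditory system find its own
boundaries.

Concretely, an epoch channel is first downsampled to the 100 Hz display
rate with a polyphase anti-aliasing resampler (`scipy.signal.
resample_poly`). Its `n` samples are then treated as a waveform at an
effective rate of `n / 1.36` samples per second (≈2205.9 Hz for a 30-s
epoch at 100 Hz) and band-limit interpolated onto a 44 100 Hz output grid
by FFT resampling. Two consequences, both tested:

- **Duration contract.** The output always has
  `round(1.36 · 44100) = 59 976` frames, i.e. 1.36 s within one output
  sample, regardless of input length.
- **Frequency mapping.** A component at `f` Hz in a 30-s input appears at
  `f · 30/1.36 ≈ f · 22.06` Hz in the clip. The 0.9–45 Hz EEG band hence
  maps to ≈19.9–992.6 Hz — effectively the 20–1000 Hz audible band.

"Sped up by approximately 95 %" is read as a duration reduction to
`1.36/30 ≈ 4.53 %` of the original (a 95.5 % reduction), realised as raw
playback-rate reinterpretation. Pitch-preserving time stretching would
not be a minimal transformation and is deliberately not offered. The
output rate is fixed at 44.1 kHz because the effective playback rate
itself (≈2.2 kHz) is poorly supported by consumer audio stacks.

Amplitude is mapped so that the ±100 μV display convention corresponds to
±1 digital full scale before conditioning; the audification is therefore
linear (`audify(αx) = α·audify(x)`), which the suite checks.

## Audio conditioning

Conditioning makes clips comfortable and comparable:

1. **Fades** — raised-cosine ramps of 10 ms (default) at each end remove
   onset/offset clicks.
2. **Loudness** — gain is applied so the RMS of the un-padded clip equals
   −12 dBFS, a conventional music-track level. −12 dB is interpreted as
   RMS re full scale (not LUFS, not peak): the simplest reading that is
   unit-testable. Normalisation is per clip; whether a session-global
   gain would be preferable is an open presentation question, and the
   choice is recorded in each clip's metadata.
3. **Peak guard** — if the −12 dBFS target would push the peak past
   −0.5 dBFS, the gain is reduced so the peak sits exactly at the
   ceiling and the RMS lands below target. High-crest-factor clips
   (epochs containing K-complexes or large slow waves) routinely engage
   the guard; low-crest Wake clips never do. The loudness contract is
   therefore a disjunction: RMS = −12 ± 0.1 dB, or peak at the guard with
   RMS below −12.
4. **Padding** — 50 ms of silence on each side against playback popping.

Fade and pad lengths are not dictated by any measurement; they are
config-exposed defaults chosen at the short end of what removes audible
clicks. A silent clip passes through unchanged with an RMS of −∞ dBFS
and a logged warning — normalising it is impossible and should not
produce noise.

WAV output is 16-bit PCM mono; round-trips are exact to one quantisation
step (2⁻¹⁵).

## PSG I/O conventions

- Units are microvolts throughout. EDF physical-dimension fields are
  trusted, with a warning logged when they disagree.
- Epoch boundaries are 0-based and half-open, `[30i, 30(i+1))` s; a
  trailing partial window is discarded (floor epoch counting).
- Re-referencing subtracts the reference trace from every other channel
  and drops the reference channel (its own re-referenced trace is
  identically zero). All channel types — EEG, EOG, EMG — are
  re-referenced uniformly; whether a montage should exempt EOG/EMG is
  montage-specific and out of scope here.
- The consensus filter keeps exactly the epochs on which two independent
  hypnograms agree, mirroring how gold-standard labels are constructed
  from double-scored datasets.

## Synthetic PSG generator

The generator exists so that every pipeline stage is testable without
recorded data. It emulates a standard reduced staging montage — F3, C3,
O1, one EOG (LOC), one chin EMG — at 200 Hz in 30-s epochs. Each EEG
channel is pink (1/f-power) background noise, flattened below 0.5 Hz to
bound drift, plus stage-specific components:

| stage | oscillation (center Hz, bw, RMS μV) | transients | EMG RMS | EOG events/s |
|-------|-------------------------------------|------------|---------|--------------|
| W     | alpha 10, 1.5, 25 (posterior-dominant) | —        | 18      | 0.15 (blinks) |
| N1    | theta 5.5, 2.5, 12; residual alpha 4 | —          | 8       | 0.05 |
| N2    | theta 5.5, 2.5, 14                  | spindles 3/epoch, K-complexes 1.5/epoch | 5 | — |
| N3    | delta 1.5, 1.0, 40; theta 8         | occasional spindles/K-complexes | 4 | — |
| REM   | theta 5.0, 2.5, 12                  | —          | 1.5 (atonia) | 0.3 (rapid) |

Spindles are Gaussian-windowed 12–14 Hz bursts of 0.5–1.5 s (~25 μV
peak); K-complexes are zero-mean biphasic ~1 s transients of ~90 μV,
fronto-centrally dominant — conventional AASM morphology, since no
amplitude or density figures are dictated by the task. Alpha is weighted
posteriorly (O1 strongest) and delta frontally. The N3 delta band is
centred at 1.5 Hz (1.0–2.0 Hz) so that, under the ×22.06 frequency
mapping, essentially all rendered power lands above 20 Hz; amplitudes
are chosen so traces render on a ±100 μV display with only slow waves
and transients exceeding the scale. Event counts are Poisson with the
tabulated densities; N2 is guaranteed at least one spindle.

All generators are deterministic for a fixed integer seed (epoch seeds
within a recording are spawned from one `SeedSequence`). Epoch
boundaries in a concatenated recording get a 20 ms fade-out/fade-in so
the signal is continuous while the total duration stays exactly
`30 · n_epochs` s.

What the generator does **not** model: true cortical source geometry and
volume conduction, inter-channel correlation structure beyond shared
oscillations, artifacts (movement, sweat, mains hum), stage transitions
within an epoch, or any learning/multisensory effects in the listener.
Tests passing on this data show the pipeline's signal processing and
statistics are correct, and that the stages are in principle separable;
they say nothing about human performance on real recordings.

Simulated raters respond to each epoch by sampling the row of a 5×5
row-stochastic confusion matrix indexed by the true stage. For a
symmetric matrix with correct-probability `p` and uniform truth, the
expected kappa is `(p − 0.2)/0.8`, which the suite recovers within
3 Monte-Carlo standard errors at n = 5000 for p ∈ {0.3, 0.6, 0.9}.
Reaction times are lognormal — strictly positive and right-skewed, the
standard shape for RT data — moment-matched to a given mean and SD;
defaults (mean 5.5 s, SD 2.1 s) are the practice-block statistics of
known attentive stagers, the natural operating point for simulations.

## Scoring statistics

- **Cohen's kappa** is computed from the 5×5 confusion matrix,
  `κ = (p_o − p_e)/(1 − p_e)`. It is *undefined* — a typed `None`, never
  a silent zero — when every epoch in the block truly has the same stage
  (the convention for single-class blocks, where per-stage percent
  correct is the right measure instead), or when `p_e = 1`.
- **Per-stage accuracy** is `100 · correct / true instances` for each
  stage present in the block; absent stages are omitted rather than
  reported as 0 or NaN. Prevalence-weighted per-stage accuracies
  reconstruct overall percent correct exactly (tested).
- **RT outlier filter**: trials outside mean ± 2σ are dropped, with mean
  and population σ computed once on the unfiltered set — not iterated,
  which would have no principled stopping point. With σ = 0 the bound
  holds at equality and nothing is removed. The filter is applied per
  participant-block (config-switchable), and RT analyses include correct
  trials only.
- **Practice gate**: a practice block fails if the median RT is strictly
  below 2 s (the bot criterion); a median of exactly 2 s passes.
- **Paired comparison**: two-sided Wilcoxon signed-rank, exact null for
  n ≤ 25, with zero differences dropped before ranking (the original
  signed-rank convention). The alternative `permutation` method
  sign-flips the signed-rank statistic over ≥10⁴ seeded draws and agrees
  with the exact null to Monte-Carlo error.
- **Experience stratification** groups participants into five bins of
  self-reported polysomnograms staged per year (1-10, 11-20, 21-40,
  41-80, >80) and produces per-bin paired (sound, no-sound) kappa tables.
  Empty bins are omitted with a notice.

## Problem sizes and numerical choices

The test suite exercises: 200 random response sets against a double-loop
kappa oracle; full 2ⁿ enumeration of signed-rank nulls up to n = 12;
rater-recovery at n = 5000 trials; a 30-replicate simulated cohort
(40 participants in the 14/8/10/5/3 bin shape, 30-epoch blocks) for the
selective-effect power check; and 100 synthetic epochs for the
stage-separability check. These sizes put Monte-Carlo error well inside
the asserted tolerances while keeping the suite fast.

FFT bin tolerance for frequency-mapping assertions is one bin
(`44100/59976 ≈ 0.735` Hz). Loudness assertions use ±0.1 dB. EDF test
fixtures are written by a minimal single-record EDF emitter in the test
suite (synthetic data only).

## Known limitations

- The audification assumes the input epoch is exactly the display-rate
  signal; no artifact rejection or display filtering is applied first.
- Per-clip loudness normalisation discards relative amplitude information
  *between* epochs (an N3 epoch does not sound louder than an N1 epoch,
  only lower-pitched); a session-global gain mode would preserve it.
- The synthetic generator's stage separability is by construction; it
  cannot validate staging difficulty, inter-rater disagreement patterns,
  or learning effects in human listeners.
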