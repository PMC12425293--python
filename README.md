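# sleepsonify

Audification of sleep-EEG epochs into short audio clips, plus the
statistics used to evaluate human sleep-staging performance, exercised on
a built-in synthetic polysomnography (PSG) generator.

Sleep staging classifies each 30-second PSG epoch into one of five AASM
stages — Wake, N1, N2, N3, REM — from EEG, EOG and chin-EMG traces.
`sleepsonify` renders one EEG channel of an epoch as sound so a scorer
can *hear* the stage: the raw waveform is played back ~22× faster,
compressing 30 s of signal into a 1.36 s clip (a ≈95.5 % duration
reduction). Under this mapping a component at `f` Hz in the EEG appears
at `f · 30/1.36` Hz in the clip, so the 0.9–45 Hz EEG band lands in the
audible ≈20–1000 Hz range — alpha rhythm becomes a ~220 Hz tone, sleep
spindles brief ~290 Hz chirps, slow waves a low ~30 Hz rumble. The clip
is then conditioned for playback: raised-cosine fades and silence padding
against popping, and RMS loudness normalisation to −12 dBFS (a typical
music-track level) with a −0.5 dBFS peak guard against clipping.

The package has four library modules and a CLI:

- **`sleepsonify.eeg_io`** — read PSG recordings (EDF via MNE, or a plain
  columnar text format), re-reference to a chosen electrode (e.g. the
  right ear), cut into 30 s epochs, read/write hypnograms, and keep only
  epochs on which two independent stagers agree (consensus filter).
- **`sleepsonify.sonifier`** — anti-aliased downsampling to the 100 Hz
  display rate, the audification itself, audio conditioning, 16-bit PCM
  WAV output, and band-power summaries.
- **`sleepsonify.synth_psg`** — stage-characteristic synthetic PSG
  (posterior alpha in Wake, spindles and K-complexes in N2, high-amplitude
  delta in N3, EMG atonia and rapid eye movements in REM) and simulated
  raters with a configurable 5×5 stage-confusion matrix and lognormal
  reaction times.
- **`sleepsonify.scoring`** — Cohen's kappa
  `κ = (p_o − p_e)/(1 − p_e)` (undefined, by convention, when the true
  stage never varies in a block), per-stage percent correct, ±2σ
  reaction-time outlier exclusion, correct-trials-only filtering, a
  practice-block bot gate (median RT < 2 s fails), exact Wilcoxon
  signed-rank / sign-flip permutation paired comparisons, and
  stratification of participants by staging experience.

## Worked example

Generate a 30-epoch synthetic block, sonify its first epoch, and score
the simulated rater's responses:

```sh
sleepsonify synth --out block --seed 1
sleepsonify sonify --in block/recording.txt --hypnogram block/hypnogram.txt \
    --epoch 0 --out wavs
sleepsonify score --responses block/responses.csv --out report.json
```

`wavs/manifest.json` records, for the rendered N2 epoch:

```
"duration_s": 1.46,      # 1.36 s of audio + 50 ms padding each side
"rms_dbfs": -12.2025     # just under -12: a K-complex tripped the peak guard
```

and `report.json` contains, for the simulated rater (70 % correct-stage
probability):

```
kappa 0.659   n_trials 30   median RT 5.50 s
```

κ ≈ 0.66 is the chance-corrected agreement between the simulated
responses and the true stages; the median reaction time of 5.5 s matches
the rater model's default, which is typical of attentive human stagers.

The same operations are available as library calls:

```python
from sleepsonify import synth_epoch, sonify_epoch, write_wav

epoch = synth_epoch("N3", seed=0)              # 5 channels, 30 s @ 200 Hz
clip = sonify_epoch(epoch.channel("O1"), epoch.fs)
write_wav(clip, "n3.wav")                      # low ~30 Hz rumble
```

## Columnar text recording format

Lines starting with `#` carry metadata (`# fs=200`, optional
`# reference=A2`), followed by one whitespace-separated header row of
channel names and one row of microvolt samples per time point.
Hypnograms are one stage token (`W`, `N1`, `N2`, `N3`, `REM`) per line.
Response tables are CSV with columns
`participant_id,block,epoch,true_stage,response,rt_seconds`.

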