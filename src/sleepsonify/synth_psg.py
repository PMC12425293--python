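"""Synthetic polysomnography and simulated stagers.

Generates stage-characteristic 5-channel PSG epochs (F3, C3, O1, LOC chin
EMG layout, 30 s at 200 Hz) so that every downstream component can be
exercised without any recorded data.  The signal model is deliberately
phenomenological, not a forward model of cortical sources: pink (1/f)
background EEG plus stage-specific narrowband oscillations and transient
waveforms —

* Wake: a prominent ~10 Hz posterior alpha rhythm (strongest on O1),
  high chin-EMG tone, occasional eye blinks.
* N1: low-amplitude mixed-frequency theta, attenuated alpha.
* N2: theta background with sleep spindles (12-14 Hz bursts) and
  K-complexes (large biphasic ~1 s transients).
* N3: high-amplitude slow delta (0.5-2 Hz) dominating all channels.
* REM: mixed theta, near-atonic EMG, frequent rapid eye-movement
  deflections on the EOG.

Amplitudes are chosen so traces render sensibly on a +/-100 uV display.
All generators are deterministic for a fixed integer seed.

Simulated raters answer each epoch by sampling a row-stochastic 5x5
confusion matrix and draw reaction times from a moment-matched lognormal,
emulating the response tables a staging experiment produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .eeg_io import EPOCH_SECONDS, STAGES, Epoch, Hypnogram, Recording, validate_stage
from .scoring import ResponseSet, Trial

#: Channel layout of a synthetic epoch (3 EEG, 1 EOG, 1 chin EMG).
CHANNELS = ("F3", "C3", "O1", "LOC", "EMG")

#: Relative strength of each oscillation band on each EEG channel:
#: alpha is posterior-dominant, delta frontal-dominant.
_TOPOGRAPHY = {
    "alpha": {"F3": 0.5, "C3": 0.8, "O1": 1.3},
    "delta": {"F3": 1.2, "C3": 1.0, "O1": 0.8},
    "other": {"F3": 1.0, "C3": 1.0, "O1": 1.0},
}


@dataclass(frozen=True)
class StageModel:
    """Generative parameters of one sleep stage.

    oscillations : list of (center_hz, bandwidth_hz, rms_uv) narrowband
        components added to the pink background.
    spindle_density / kcomplex_density : expected transient events per
        30-s epoch.
    emg_tone_uv : RMS of the chin-EMG tone.
    eog_rate : eye-movement events per second on the EOG channel.
    background_uv : RMS of the 1/f background EEG.
    """

    stage: str
    oscillations: tuple[tuple[float, float, float], ...] = ()
    spindle_density: float = 0.0
    kcomplex_density: float = 0.0
    emg_tone_uv: float = 5.0
    eog_rate: float = 0.0
    background_uv: float = 8.0

    def __post_init__(self) -> None:
        validate_stage(self.stage)
        for c, bw, a in self.oscillations:
            if a < 0 or bw <= 0:
                raise ValueError("oscillation amplitude/bandwidth must be >= 0")
        if self.spindle_density < 0 or self.kcomplex_density < 0:
            raise ValueError("event densities must be >= 0")


#: Defaults follow AASM stage phenomenology; the source data give no
#: amplitude or density figures, so these are conventional values.
DEFAULT_STAGE_MODELS: dict[str, StageModel] = {
    "W": StageModel("W", oscillations=((10.0, 1.5, 25.0),),
                    emg_tone_uv=18.0, eog_rate=0.15, background_uv=6.0),
    "N1": StageModel("N1", oscillations=((5.5, 2.5, 12.0), (10.0, 1.5, 4.0)),
                     emg_tone_uv=8.0, eog_rate=0.05, background_uv=8.0),
    "N2": StageModel("N2", oscillations=((5.5, 2.5, 14.0),),
                     spindle_density=3.0, kcomplex_density=1.5,
                     emg_tone_uv=5.0, background_uv=9.0),
    "N3": StageModel("N3", oscillations=((1.5, 1.0, 40.0), (5.5, 2.5, 8.0)),
                     spindle_density=0.5, kcomplex_density=0.5,
                     emg_tone_uv=4.0, background_uv=10.0),
    "REM": StageModel("REM", oscillations=((5.0, 2.5, 12.0),),
                      emg_tone_uv=1.5, eog_rate=0.3, background_uv=8.0),
}


@dataclass(frozen=True)
class RaterModel:
    """A simulated sleep stager.

    confusion : 5x5 row-stochastic matrix, P(response | true stage), rows
        ordered as ``STAGES``.
    rt_mean, rt_sd : mean and SD (seconds) of the lognormal reaction-time
        distribution.  Defaults are the practice-block statistics of known
        valid human stagers (median-RT mean 5.5 s, SD 2.1 s).
    """

    confusion: np.ndarray
    rt_mean: float = 5.5
    rt_sd: float = 2.1
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion, dtype=float)
        object.__setattr__(self, "confusion", c)
        if c.shape != (5, 5):
            raise ValueError(f"confusion matrix must be 5x5, got {c.shape}")
        if np.any(c < 0) or not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must be non-negative and sum to 1")
        if self.rt_mean <= 0 or self.rt_sd < 0:
            raise ValueError("rt_mean must be > 0 and rt_sd >= 0")


def symmetric_confusion(p_correct: float) -> np.ndarray:
    """5x5 matrix with ``p_correct`` on the diagonal, rest uniform."""
    if not 0.0 <= p_correct <= 1.0:
        raise ValueError("p_correct must be in [0, 1]")
    off = (1.0 - p_correct) / 4.0
    return np.full((5, 5), off) + (p_correct - off) * np.eye(5)


# ---------------------------------------------------------------------------
# signal building blocks


def _pink_noise(n: int, rng: np.random.Generator, rms: float,
                f_lo: float = 0.5, fs: float = 200.0) -> np.ndarray:
    """1/f-power background noise, flat below ``f_lo`` to bound DC drift."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, f_lo))
    shaping[0] = 0.0  # remove DC
    y = np.fft.irfft(spec * shaping, n)
    return y * (rms / np.std(y))


def _narrowband(n: int, rng: np.random.Generator, center: float,
                bandwidth: float, rms: float, fs: float) -> np.ndarray:
    """Band-limited Gaussian oscillation of given RMS."""
    if rms == 0:
        return np.zeros(n)
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, fs / 2.0 - 0.1)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return y * (rms / np.std(y))


def _spindle(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-windowed 12-14 Hz burst, 0.5-1.5 s, ~25 uV peak."""
    dur = rng.uniform(0.5, 1.5)
    f = rng.uniform(12.0, 14.0)
    t = np.arange(int(dur * fs)) / fs
    envelope = np.exp(-0.5 * ((t - dur / 2) / (dur / 6)) ** 2)
    return 25.0 * envelope * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))


def _k_complex(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Biphasic ~1 s transient with >= 75 uV peak-to-peak."""
    dur = rng.uniform(0.8, 1.2)
    t = np.linspace(0, 1, int(dur * fs))
    # zero-mean biphasic wave: sharp negative deflection, positive rebound
    wave = -np.sin(2 * np.pi * t) * np.sin(np.pi * t)
    return 90.0 * wave / np.max(np.abs(wave))


def _eog_event(fs: float, rng: np.random.Generator, rapid: bool) -> np.ndarray:
    """One eye-movement deflection: fast ramp + decay (saccade or blink)."""
    dur = rng.uniform(0.25, 0.45) if rapid else rng.uniform(0.4, 0.7)
    n = int(dur * fs)
    t = np.linspace(0, 1, n)
    rise = min(0.15 if rapid else 0.3, 0.9)
    shape = np.where(t < rise, t / rise, np.exp(-4 * (t - rise)))
    sign = rng.choice([-1.0, 1.0])
    return sign * rng.uniform(60.0, 120.0) * shape


def _place_events(x: np.ndarray, events: list[np.ndarray],
                  rng: np.random.Generator) -> None:
    """Add transient waveforms at random positions (in place)."""
    for ev in events:
        if len(ev) >= len(x):
            continue
        start = rng.integers(0, len(x) - len(ev))
        x[start:start + len(ev)] += ev


# ---------------------------------------------------------------------------
# generators


def synth_epoch(stage: str, seed: int,
                models: dict[str, StageModel] | None = None,
                fs: float = 200.0) -> Epoch:
    """Generate one stage-characteristic 30-s, 5-channel epoch.

    Deterministic for fixed ``(stage, seed)``; different stages at the
    same seed produce different signals.
    """
    validate_stage(stage)
    models = models or DEFAULT_STAGE_MODELS
    if stage not in models:
        raise ValueError(f"no StageModel supplied for stage {stage!r}")
    model = models[stage]
    rng = np.random.default_rng([int(seed), STAGES.index(stage)])
    n = int(round(EPOCH_SECONDS * fs))

    # shared oscillatory components, weighted per channel by topography
    components = []
    for center, bw, amp in model.oscillations:
        wave = _narrowband(n, rng, center, bw, amp, fs)
        if 8.0 <= center <= 13.0:
            topo = _TOPOGRAPHY["alpha"]
        elif center <= 4.0:
            topo = _TOPOGRAPHY["delta"]
        else:
            topo = _TOPOGRAPHY["other"]
        components.append((wave, topo))

    n_spindles = rng.poisson(model.spindle_density)
    if model.spindle_density >= 1.0:
        n_spindles = max(n_spindles, 1)
    n_kc = rng.poisson(model.kcomplex_density)
    spindles = [_spindle(fs, rng) for _ in range(n_spindles)]
    kcs = [_k_complex(fs, rng) for _ in range(n_kc)]

    eeg = {}
    for name in ("F3", "C3", "O1"):
        x = _pink_noise(n, rng, model.background_uv, fs=fs)
        for wave, topo in components:
            x = x + topo[name] * wave
        # transients are fronto-central dominant
        gain = {"F3": 1.0, "C3": 1.0, "O1": 0.6}[name]
        _place_events(x, [gain * s for s in spindles], rng)
        _place_events(x, [gain * k for k in kcs], rng)
        eeg[name] = x

    # EOG: attenuated frontal EEG + deflection events
    eog = 0.3 * eeg["F3"] + _pink_noise(n, rng, 4.0, fs=fs)
    n_eog = rng.poisson(model.eog_rate * EPOCH_SECONDS)
    rapid = stage == "REM"
    _place_events(eog, [_eog_event(fs, rng, rapid) for _ in range(n_eog)], rng)

    # chin EMG: broadband high-frequency tone
    sos = sps.butter(4, [20.0, min(95.0, fs / 2 - 1)], btype="bandpass",
                     fs=fs, output="sos")
    emg = sps.sosfiltfilt(sos, rng.standard_normal(n))
    emg *= model.emg_tone_uv / np.std(emg)

    samples = np.stack([eeg["F3"], eeg["C3"], eeg["O1"], eog, emg])
    return Epoch(samples=samples, channel_names=list(CHANNELS), fs=fs,
                 index=0, true_stage=stage)


def synth_recording(hypnogram: Hypnogram, seed: int,
                    models: dict[str, StageModel] | None = None,
                    fs: float = 200.0,
                    crossfade_ms: float = 20.0) -> tuple[Recording, Hypnogram]:
    """Concatenate per-stage epochs into a continuous recording.

    Epoch boundaries get a short fade-out/fade-in so the concatenation has
    no step discontinuities; total duration is exactly
    ``30 * len(hypnogram)`` seconds.
    """
    if len(hypnogram) == 0:
        return (Recording(samples=np.zeros((len(CHANNELS), 0)),
                          channel_names=list(CHANNELS), fs=fs),
                Hypnogram([]))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(hypnogram))
    blocks = [synth_epoch(stage, int(s), models, fs)
              for stage, s in zip(hypnogram, child_seeds)]
    n_fade = int(round(crossfade_ms / 1000.0 * fs))
    if n_fade > 1:
        ramp = np.linspace(0.0, 1.0, n_fade)
        for i, ep in enumerate(blocks):
            if i > 0:
                ep.samples[:, :n_fade] *= ramp
            if i < len(blocks) - 1:
                ep.samples[:, -n_fade:] *= ramp[::-1]
    data = np.concatenate([ep.samples for ep in blocks], axis=1)
    rec = Recording(samples=data, channel_names=list(CHANNELS), fs=fs)
    return rec, Hypnogram(list(hypnogram))


def synth_responses(truth: list[str] | Hypnogram, rater: RaterModel,
                    block_id: str = "sound",
                    participant_id: str = "sim") -> ResponseSet:
    """Simulate one rater staging a block of epochs.

    Each response is drawn from the confusion-matrix row of the true
    stage; reaction times are lognormal with the rater's mean/SD
    (moment-matched, hence strictly positive).  Deterministic for a fixed
    ``rater.seed``.
    """
    truth = [validate_stage(s) for s in truth]
    if not truth:
        raise ValueError("truth sequence is empty")
    rng = np.random.default_rng(rater.seed)
    # lognormal parameters from the distribution's own mean/SD
    m, s = rater.rt_mean, max(rater.rt_sd, 1e-9)
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    trials = []
    for i, stage in enumerate(truth):
        row = rater.confusion[STAGES.index(stage)]
        response = STAGES[rng.choice(5, p=row)]
        rt = float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))
        trials.append(Trial(epoch_index=i, true_stage=stage,
                            response=response, rt=rt))
    return ResponseSet(trials=trials, block_id=block_id,
                       participant_id=participant_id)
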