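"""Minimal audification of EEG epochs into short audio clips.

The transform deliberately avoids musical or feature-mapping schemes: the
raw waveform of one channel of one 30-s epoch is played back at a greatly
accelerated rate, so that the clip *is* the data, only faster.  A 30-s
window compressed to 1.36 s corresponds to a ~22x speed-up (a ~95.5%
duration reduction), which shifts the 0.9-45 Hz EEG band into the audible
~20-1000 Hz range.  The clip is then conditioned for playback: raised-
cosine fades against popping, silence padding, and RMS loudness
normalisation to a standard music-track level with a peak guard against
clipping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Display scale convention: signals are shown at +/-100 microvolts full
#: scale, so 100 uV maps to digital full scale before loudness adjustment.
DISPLAY_SCALE_UV = 100.0


@dataclass(frozen=True)
class SonifyParams:
    """Parameters of the audification and conditioning chain.

    display_fs : Hz the epoch is downsampled to before audification (100).
    target_duration : length of the rendered clip in seconds (1.36).
    out_fs : output audio sampling rate in Hz (44100).
    loudness_dbfs : RMS target of the conditioned clip, dB re full scale (-12).
    fade_ms : raised-cosine fade-in/out length in milliseconds.
    pad_ms : leading/trailing silence in milliseconds.
    peak_guard_dbfs : peak ceiling; loudness gain is reduced if the peak
        would exceed this level.
    """

    display_fs: float = 100.0
    target_duration: float = 1.36
    out_fs: int = 44100
    loudness_dbfs: float = -12.0
    fade_ms: float = 10.0
    pad_ms: float = 50.0
    peak_guard_dbfs: float = -0.5

    def __post_init__(self) -> None:
        if self.target_duration <= 0:
            raise ValueError("target_duration must be positive")
        if self.loudness_dbfs >= 0:
            raise ValueError("loudness_dbfs must be negative (below full scale)")
        if self.out_fs <= 0:
            raise ValueError("out_fs must be positive")


@dataclass
class AudioClip:
    """Mono audio waveform with loudness and provenance metadata."""

    samples: np.ndarray
    fs: float
    rms_dbfs: float | None = None
    source_epoch: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip is mono: samples must be 1-D")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def rms_dbfs(x: np.ndarray) -> float:
    """RMS level in dB relative to digital full scale; -inf for silence."""
    r = float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0
    return 20.0 * math.log10(r) if r > 0 else -math.inf


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass and resample ``x`` from ``fs_in`` to ``fs_out`` Hz.

    Output length is ``round(n * fs_out / fs_in)``.  Upsampling is refused
    here; rate raising happens only inside :func:`audify`.
    """
    if fs_out > fs_in:
        raise ValueError(
            f"downsample target {fs_out} Hz exceeds input rate {fs_in} Hz"
        )
    x = np.asarray(x, dtype=float)
    if fs_out == fs_in:
        return x.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(len(x) * fs_out / fs_in))
    return y[:n_out]


def audify(x: np.ndarray, params: SonifyParams | None = None,
           source_epoch: int | None = None) -> AudioClip:
    """Render one channel of one epoch as a time-compressed audio clip.

    The ``n`` input samples (taken to be at ``params.display_fs``) are
    reinterpreted at an effective playback rate of ``n / target_duration``
    samples per second and band-limit interpolated onto the ``out_fs``
    grid.  A spectral component at ``f`` Hz in a 30-s input therefore
    appears at ``f * 30 / target_duration`` Hz in the output.  Amplitude is
    mapped so that the +/-100 uV display scale corresponds to +/-1 full
    scale; the transform is linear, so ``audify(a*x) == a*audify(x)``.
    """
    params = params or SonifyParams()
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot audify an empty signal")
    n_out = int(round(params.target_duration * params.out_fs))
    if not np.any(x):
        y = np.zeros(n_out)
    else:
        # FFT resampling = ideal band-limited interpolation from the
        # playback grid (rate n/target_duration) onto the out_fs grid.
        y = sps.resample(x, n_out)
    y = y / DISPLAY_SCALE_UV
    return AudioClip(samples=y, fs=params.out_fs, source_epoch=source_epoch)


def condition_audio(clip: AudioClip, params: SonifyParams | None = None) -> AudioClip:
    """Prepare a raw clip for playback: fade, normalise loudness, pad.

    Raised-cosine fades of ``fade_ms`` are applied at both ends, gain is
    set so the RMS of the (un-padded) clip hits ``loudness_dbfs`` — reduced
    uniformly if the resulting peak would exceed ``peak_guard_dbfs`` — and
    ``pad_ms`` of silence is attached on each side.  A silent clip is
    passed through unchanged with ``rms_dbfs = -inf``.
    """
    params = params or SonifyParams()
    y = np.asarray(clip.samples, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("clip contains non-finite samples")
    if not np.any(y):
        logger.warning("conditioning a silent clip; returning it unchanged")
        return replace(clip, samples=y.copy(), rms_dbfs=-math.inf)

    y = y.copy()
    n_fade = int(round(params.fade_ms / 1000.0 * clip.fs))
    n_fade = min(n_fade, len(y) // 2)
    if n_fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        y[:n_fade] *= ramp
        y[-n_fade:] *= ramp[::-1]

    target_rms = 10.0 ** (params.loudness_dbfs / 20.0)
    peak_ceiling = 10.0 ** (params.peak_guard_dbfs / 20.0)
    cur_rms = float(np.sqrt(np.mean(np.square(y))))
    gain = target_rms / cur_rms
    peak = float(np.max(np.abs(y))) * gain
    if peak > peak_ceiling:
        gain *= peak_ceiling / peak
    y *= gain

    measured = rms_dbfs(y)
    n_pad = int(round(params.pad_ms / 1000.0 * clip.fs))
    pad = np.zeros(n_pad)
    return AudioClip(
        samples=np.concatenate([pad, y, pad]),
        fs=clip.fs,
        rms_dbfs=measured,
        source_epoch=clip.source_epoch,
    )


def sonify_epoch(x: np.ndarray, fs: float,
                 params: SonifyParams | None = None,
                 source_epoch: int | None = None,
                 condition: bool = True) -> AudioClip:
    """Full chain for one epoch channel: downsample, audify, condition."""
    params = params or SonifyParams()
    if fs > params.display_fs:
        x = downsample(x, fs, params.display_fs)
    elif fs < params.display_fs:
        raise ValueError(
            f"signal rate {fs} Hz is below display rate {params.display_fs} Hz"
        )
    clip = audify(x, params, source_epoch=source_epoch)
    return condition_audio(clip, params) if condition else clip


def write_wav(clip: AudioClip, path: str | Path) -> None:
    """Write a clip as 16-bit PCM mono WAV."""
    y = np.asarray(clip.samples, dtype=float)
    if len(y) and float(np.max(np.abs(y))) > 1.0:
        raise ValueError(
            "samples exceed [-1, 1]; run condition_audio before writing"
        )
    pcm = np.round(y * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(clip.fs), pcm)


def read_wav(path: str | Path) -> AudioClip:
    """Read a 16-bit PCM mono WAV back into an AudioClip in [-1, 1]."""
    fs, pcm = wavfile.read(str(path))
    if pcm.ndim != 1:
        raise ValueError("expected mono WAV")
    return AudioClip(samples=pcm.astype(float) / 32767.0, fs=float(fs))


def spectral_summary(clip: AudioClip, band: tuple[float, float]) -> float:
    """Fraction of total signal power falling in ``band`` (Hz), in [0, 1].

    Parseval-consistent: band powers over a partition of [0, fs/2] sum to 1.
    """
    y = np.asarray(clip.samples, dtype=float)
    if not np.any(y):
        raise ValueError("spectral summary of a silent clip is undefined")
    lo, hi = band
    spec = np.abs(np.fft.rfft(y)) ** 2
    freqs = np.fft.rfftfreq(len(y), d=1.0 / clip.fs)
    total = float(spec.sum())
    in_band = float(spec[(freqs >= lo) & (freqs <= hi)].sum())
    return in_band / total
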