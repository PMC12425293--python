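"""Shared fixtures: synthetic recordings and a minimal EDF writer.

No binary fixtures ship with the repo; everything is generated at test
time.  The EDF writer below emits just enough of the format (fixed
256-byte header, per-signal headers, int16 data records) to exercise the
EDF reading path against files of known content.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from sleepsonify import Hypnogram, Recording, synth_recording


def write_minimal_edf(path: Path, channels: dict[str, np.ndarray],
                      fs: float, phys_range: float = 1000.0) -> None:
    """Write a single-record EDF file (synthetic, test use only).

    All channels must share one length equal to ``record_seconds * fs``
    for an integral number of seconds.  Samples are in microvolts and are
    quantised to the int16 digital range.
    """
    names = list(channels)
    n_samples = len(next(iter(channels.values())))
    record_seconds = int(round(n_samples / fs))
    assert abs(record_seconds * fs - n_samples) < 1e-9, "need whole seconds"
    ns = len(names)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        assert len(b) <= width
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.01", 8), pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8), pad("", 44),
        pad("1", 8), pad(str(record_seconds), 8), pad(str(ns), 4),
    ])
    sig = b"".join(pad(n, 16) for n in names)
    sig += b"".join(pad("", 80) for _ in names)
    sig += b"".join(pad("uV", 8) for _ in names)
    sig += b"".join(pad(str(-phys_range), 8) for _ in names)
    sig += b"".join(pad(str(phys_range), 8) for _ in names)
    sig += b"".join(pad("-32768", 8) for _ in names)
    sig += b"".join(pad("32767", 8) for _ in names)
    sig += b"".join(pad("", 80) for _ in names)
    sig += b"".join(pad(str(n_samples), 8) for _ in names)
    sig += b"".join(pad("", 32) for _ in names)

    scale = 32767.0 / phys_range
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for n in names:
            dig = np.clip(np.round(channels[n] * scale), -32768, 32767)
            fh.write(struct.pack(f"<{n_samples}h", *dig.astype(np.int16)))


@pytest.fixture
def edf_writer():
    return write_minimal_edf


@pytest.fixture
def small_recording() -> Recording:
    """Deterministic 2-channel 95 s recording at 200 Hz."""
    rng = np.random.default_rng(42)
    n = 95 * 200
    return Recording(
        samples=rng.normal(scale=10.0, size=(2, n)),
        channel_names=["C3", "A2"],
        fs=200.0,
    )


@pytest.fixture(scope="session")
def synth_block():
    """A 4-epoch synthetic recording covering distinct stages."""
    hyp = Hypnogram(["W", "N2", "N3", "REM"])
    rec, hyp = synth_recording(hyp, seed=7)
    return rec, hyp
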