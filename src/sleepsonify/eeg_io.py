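"""Reading, re-referencing, epoching and labelling of polysomnography data.

Signals are held in microvolts throughout.  Two on-disk formats are
supported: EDF (the clinical interchange standard, read through MNE) and a
plain columnar text format (``# fs=...`` comment lines, a header row of
channel names, then whitespace-separated numeric rows) that keeps fixtures
human-readable and binary-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The five AASM sleep-stage labels, in conventional order.
STAGES = ("W", "N1", "N2", "N3", "REM")

#: Scoring epoch length in seconds (AASM convention).
EPOCH_SECONDS = 30.0


def validate_stage(label: str) -> str:
    """Return ``label`` if it is one of the five AASM stages, else raise."""
    if label not in STAGES:
        raise ValueError(f"unknown sleep stage {label!r}; expected one of {STAGES}")
    return label


@dataclass
class Recording:
    """Multi-channel PSG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal data in microvolts.
    channel_names : list of str
        Unique channel labels, one per row of ``samples``.
    fs : float
        Sampling rate in Hz.
    reference : str
        Name of the reference channel, or ``"none"`` when unknown/native.
    """

    samples: np.ndarray
    channel_names: list[str]
    fs: float
    reference: str = "none"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"duplicate channel names in {self.channel_names}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector for a named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in recording (have {self.channel_names})"
            ) from None
        return self.samples[i]


@dataclass
class Epoch:
    """One 30-second scoring window of a recording."""

    samples: np.ndarray  # (n_channels, 30*fs), microvolts
    channel_names: list[str]
    fs: float
    index: int
    true_stage: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        expected = int(round(EPOCH_SECONDS * self.fs))
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"epoch must span exactly {EPOCH_SECONDS:g} s "
                f"({expected} samples at {self.fs:g} Hz), "
                f"got {self.samples.shape[1]}"
            )
        if self.true_stage is not None:
            validate_stage(self.true_stage)

    @property
    def start_time(self) -> float:
        """Offset of the epoch from recording start, in seconds."""
        return EPOCH_SECONDS * self.index

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch") from None
        return self.samples[i]


@dataclass
class Hypnogram:
    """Per-epoch sequence of sleep-stage labels."""

    labels: list[str] = field(default_factory=list)
    epoch_len: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.labels = [validate_stage(s) for s in self.labels]

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, Hypnogram):
            return self.labels == other.labels and self.epoch_len == other.epoch_len
        return NotImplemented


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a PSG recording from EDF or columnar text.

    ``format`` is ``"edf"`` or ``"columnar-text"``; when omitted it is
    inferred from the file suffix (``.edf`` -> EDF, anything else -> text).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "columnar-text"
    if format == "edf":
        return _read_edf(path)
    if format == "columnar-text":
        return _read_columnar(path)
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: heavy import, EDF path only

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    except Exception as exc:  # mne raises a mix of types for bad files
        raise ValueError(f"could not parse {path} as EDF: {exc}") from exc
    units = getattr(raw._orig_units, "values", lambda: [])()
    for u in units:
        if u and u.lower() not in ("uv", "µv", "μv", "n/a"):
            logger.warning("EDF channel unit %r is not microvolts; trusting header", u)
    data = raw.get_data() * 1e6  # MNE returns volts
    return Recording(
        samples=data,
        channel_names=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
    )


def _read_columnar(path: Path) -> Recording:
    fs = None
    reference = "none"
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "fs":
                        fs = float(val)
                    elif key == "reference":
                        reference = val
                continue
            if header is None:
                header = line.split()
                continue
            fields = line.split()
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
    if header is None:
        raise ValueError(f"{path}: empty file, no header row")
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' metadata line")
    if not rows:
        raise ValueError(f"{path}: header but no sample rows")
    return Recording(
        samples=np.asarray(rows, dtype=float).T,
        channel_names=header,
        fs=fs,
        reference=reference,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the columnar text format."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write(f"# reference={rec.reference}\n")
        fh.write("\t".join(rec.channel_names) + "\n")
        for row in rec.samples.T:
            fh.write("\t".join(f"{x:.4f}" for x in row) + "\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram: one stage token (W/N1/N2/N3/REM) per line."""
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok or tok.startswith("#"):
                continue
            if tok not in STAGES:
                raise ValueError(
                    f"{path}:{lineno}: unknown stage token {tok!r}; "
                    f"expected one of {STAGES}"
                )
            labels.append(tok)
    return Hypnogram(labels)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in hyp.labels:
            fh.write(label + "\n")


# ---------------------------------------------------------------------------
# transforms


def rereference(rec: Recording, ref_channel: str) -> Recording:
    """Re-reference all channels to ``ref_channel``.

    Each remaining channel becomes ``channel - ref``; the reference channel
    itself is dropped (its re-referenced trace is identically zero).  A
    recording already referenced to ``ref_channel`` is returned unchanged,
    so the operation is idempotent.  All channel types are re-referenced
    uniformly.
    """
    if rec.reference == ref_channel:
        return replace(rec, samples=rec.samples.copy(),
                       channel_names=list(rec.channel_names))
    if ref_channel not in rec.channel_names:
        raise KeyError(
            f"reference channel {ref_channel!r} not in recording "
            f"(have {rec.channel_names})"
        )
    ref = rec.channel(ref_channel)
    keep = [n for n in rec.channel_names if n != ref_channel]
    data = np.stack([rec.channel(n) - ref for n in keep])
    return Recording(samples=data, channel_names=keep, fs=rec.fs,
                     reference=ref_channel)


def extract_epochs(
    rec: Recording,
    epoch_len: float = EPOCH_SECONDS,
    hypnogram: Hypnogram | None = None,
) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping scoring epochs.

    Epoch ``i`` covers the half-open interval ``[epoch_len*i,
    epoch_len*(i+1))`` seconds; a trailing partial window is discarded.  A
    recording shorter than one epoch yields an empty list.  When a
    hypnogram is supplied its labels are attached as ``true_stage``.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    spe = int(round(epoch_len * rec.fs))  # samples per epoch
    n_epochs = rec.n_samples // spe
    if hypnogram is not None and len(hypnogram) < n_epochs:
        raise ValueError(
            f"hypnogram has {len(hypnogram)} labels for {n_epochs} epochs"
        )
    out = []
    for i in range(n_epochs):
        out.append(
            Epoch(
                samples=rec.samples[:, i * spe:(i + 1) * spe],
                channel_names=list(rec.channel_names),
                fs=rec.fs,
                index=i,
                true_stage=hypnogram[i] if hypnogram is not None else None,
            )
        )
    return out


def consensus_filter(
    labels_a: Hypnogram | Sequence[str],
    labels_b: Hypnogram | Sequence[str],
) -> list[tuple[int, str]]:
    """Keep only epochs on which two independent stagers agree.

    Returns ``(epoch_index, agreed_stage)`` pairs for exactly the indices
    where the two hypnograms carry the same label.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"hypnogram lengths differ: {len(a)} vs {len(b)}")
    return [(i, x) for i, (x, y) in enumerate(zip(a, b)) if x == y]
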