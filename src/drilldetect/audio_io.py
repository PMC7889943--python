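"""WAV and manifest I/O, segment cutting, and sliding-window labeling.

Recordings are mono 44.1 kHz WAV files (24-bit PCM as captured by the
audio interface, or IEEE float); labels live in a CSV manifest with one
row per annotated interval.  ``window_labels`` assigns a class to every
sliding analysis window by interval overlap, which turns manually cut
recordings into a supervised window-classification dataset.
"""

from __future__ import annotations

import wave
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .features import StftConfig

__all__ = [
    "CLASSES",
    "AudioClip",
    "ManifestEntry",
    "Window",
    "read_wav",
    "write_wav",
    "read_manifest",
    "write_manifest",
    "cut_segments",
    "window_labels",
]

#: the two annotation classes: drilling dense cortical bone vs. the drill
#: perforating into soft tissue.
CLASSES = ("cortical", "breakthrough")

_PCM24_FULL_SCALE = float(2**23)


class FormatError(ValueError):
    """Unsupported or malformed audio file."""


class ManifestError(ValueError):
    """Inconsistent label manifest."""


@dataclass
class AudioClip:
    """A mono audio snippet with optional class label and provenance.

    ``source_id`` identifies the originating recording (one drill hole),
    which grouped cross-validation uses as its split unit.  ``position``
    tags the sensor placement (``greater_trochanter``, ``diaphysis`` or
    ``synthetic``); it is metadata used only to separate datasets.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    source_id: str = ""
    position: str = "synthetic"
    augmented: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).reshape(-1)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES} or None")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def with_samples(self, samples: np.ndarray, augmented: bool | None = None) -> "AudioClip":
        return replace(
            self,
            samples=np.asarray(samples, dtype=np.float64),
            augmented=self.augmented if augmented is None else augmented,
        )


@dataclass(frozen=True)
class ManifestEntry:
    """One labeled interval of one WAV file."""

    file: str
    start_s: float
    end_s: float
    label: str
    source_id: str = ""
    position: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ManifestError(
                f"interval must satisfy 0 <= start < end, got "
                f"[{self.start_s}, {self.end_s}]"
            )
        if self.label not in CLASSES:
            raise ManifestError(f"label must be one of {CLASSES}")


@dataclass(frozen=True)
class Window:
    """One analysis window cut from a clip, with its overlap-derived label."""

    samples: np.ndarray
    start_s: float
    end_s: float
    label: str


def read_wav(path) -> AudioClip:
    """Read a mono WAV file, mapping integer PCM onto floats in [-1, 1].

    24-bit PCM (the acquisition format) arrives from scipy as int32 with
    the low byte zero, so division by 2^31 recovers the signed fraction.
    """
    path = Path(path)
    try:
        sr, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")
    return AudioClip(samples=samples, sample_rate=int(sr), source_id=path.stem)


def write_wav(path, clip_or_samples, sample_rate: int | None = None, subtype: str = "pcm24") -> None:
    """Write mono audio as 24-bit PCM (default) or 32-bit float WAV.

    Floats are synthesized deterministically first and quantized last:
    values are clipped to the representable range and rounded to the
    nearest 24-bit code (no dither), so the round-trip error is below
    half an LSB (2^-24 per sample).
    """
    if isinstance(clip_or_samples, AudioClip):
        samples = clip_or_samples.samples
        sample_rate = clip_or_samples.sample_rate
    else:
        samples = np.asarray(clip_or_samples, dtype=np.float64).reshape(-1)
        if sample_rate is None:
            raise ValueError("sample_rate required when passing raw samples")
    path = Path(path)
    if subtype == "float32":
        wavfile.write(path, int(sample_rate), samples.astype(np.float32))
        return
    if subtype != "pcm24":
        raise FormatError(f"unsupported subtype {subtype!r}")
    codes = np.clip(
        np.round(samples * _PCM24_FULL_SCALE), -_PCM24_FULL_SCALE, _PCM24_FULL_SCALE - 1
    ).astype(np.int32)
    as32 = (codes << 8).astype("<i4")  # little-endian, 24-bit payload in the top bytes
    raw = as32.tobytes()
    frames = b"".join(raw[i + 1 : i + 4] for i in range(0, len(raw), 4))
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(3)
        w.setframerate(int(sample_rate))
        w.writeframes(frames)


def read_manifest(path) -> list[ManifestEntry]:
    """Read a label manifest CSV (columns file,start_s,end_s,class,...)."""
    df = pd.read_csv(path)
    required = {"file", "start_s", "end_s", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns: {sorted(missing)}")
    entries = []
    for row in df.to_dict("records"):
        sid = str(row.get("source_id") or Path(str(row["file"])).stem)
        entries.append(
            ManifestEntry(
                file=str(row["file"]),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                label=str(row["class"]),
                source_id=sid,
                position=str(row.get("position", "synthetic")),
            )
        )
    return entries


def write_manifest(path, entries: list[ManifestEntry]) -> None:
    df = pd.DataFrame(
        {
            "file": [e.file for e in entries],
            "start_s": [e.start_s for e in entries],
            "end_s": [e.end_s for e in entries],
            "class": [e.label for e in entries],
            "source_id": [e.source_id for e in entries],
            "position": [e.position for e in entries],
        }
    )
    df.to_csv(path, index=False)


def cut_segments(manifest: list[ManifestEntry], root=None) -> list[AudioClip]:
    """Cut one labeled clip per manifest entry from its WAV file.

    Files are read once each; intervals outside the file duration raise a
    :class:`ManifestError`.
    """
    root = Path(root) if root is not None else None
    cache: dict[str, AudioClip] = {}
    clips = []
    for e in manifest:
        key = e.file
        if key not in cache:
            p = Path(e.file) if root is None else root / e.file
            cache[key] = read_wav(p)
        rec = cache[key]
        i0 = int(round(e.start_s * rec.sample_rate))
        i1 = int(round(e.end_s * rec.sample_rate))
        if i1 > len(rec.samples):
            raise ManifestError(
                f"{e.file}: interval [{e.start_s}, {e.end_s}] s exceeds file "
                f"duration {rec.duration:.3f} s"
            )
        clips.append(
            AudioClip(
                samples=rec.samples[i0:i1],
                sample_rate=rec.sample_rate,
                label=e.label,
                source_id=e.source_id or Path(e.file).stem,
                position=e.position,
            )
        )
    return clips


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def window_labels(
    clip: AudioClip,
    events: list[tuple[float, float]] | list,
    cfg: StftConfig,
    min_overlap_ms: float | None = None,
    step: int | None = None,
) -> list[Window]:
    """Label every sliding analysis window of a clip by event overlap.

    A window is ``breakthrough`` iff its overlap with any breakthrough
    interval is at least ``min_overlap_ms`` (default: half the window
    length, i.e. 50 ms for 100 ms windows), else ``cortical``.  ``events``
    is a list of ``(start_s, end_s)`` pairs or ``(start_s, end_s, label)``
    triples, in which case only breakthrough-labeled intervals count.

    Purely a function of the event list, the window grid and the overlap
    threshold; a clip shorter than one window yields an empty list with a
    warning.
    """
    L = cfg.window_length
    sr = clip.sample_rate
    if step is None:
        step = cfg.step
    if min_overlap_ms is None:
        min_overlap_ms = 1000.0 * L / sr / 2.0
    min_overlap_s = min_overlap_ms / 1000.0

    breakthrough_iv = []
    for ev in events:
        if len(ev) >= 3 and ev[2] != "breakthrough":
            continue
        breakthrough_iv.append((float(ev[0]), float(ev[1])))

    n = len(clip.samples)
    if n < L:
        warnings.warn("clip shorter than one analysis window; no windows produced")
        return []
    out = []
    for start in range(0, n - L + 1, step):
        t0 = start / sr
        t1 = (start + L) / sr
        hit = any(_overlap(t0, t1, b0, b1) >= min_overlap_s for b0, b1 in breakthrough_iv)
        out.append(
            Window(
                samples=clip.samples[start : start + L],
                start_s=t0,
                end_s=t1,
                label="breakthrough" if hit else "cortical",
            )
        )
    return out
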