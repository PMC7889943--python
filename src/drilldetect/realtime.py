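"""Streaming sliding-window inference and the end-to-end latency budget.

The end-to-end detection delay decomposes additively into four parts:
audio-driver latency (a hardware constant, 6.8 ms for the reference
ASIO setup), window acquisition time (``1000 * L / sample_rate`` — the
audio must exist before it can be classified), spectrogram generation
time and network inference time (both measured at run time).  The
analysis window slides in steps of ``L/4``, the same overlap used for
training framing.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .audio_io import AudioClip, read_wav
from .features import LogMelExtractor, NormalizationStats, StftConfig
from .model import Network

__all__ = ["LatencyBudget", "DetectionEvent", "total_latency", "stream_detect"]

#: driver latency of the reference audio interface (128-sample ASIO buffer).
DEFAULT_DRIVER_LATENCY_MS = 6.8


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class LatencyBudget:
    """Additive latency decomposition, all in milliseconds."""

    driver_latency: float
    window_acquisition: float
    feature_time: float
    inference_time: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise MeasurementError(f"{name} must be non-negative, got {v}")

    @property
    def total(self) -> float:
        return (
            self.driver_latency
            + self.window_acquisition
            + self.feature_time
            + self.inference_time
        )


def total_latency(
    driver_latency: float,
    window_acquisition: float,
    feature_time: float,
    inference_time: float,
) -> LatencyBudget:
    """Assemble a latency budget; ``total`` is the exact component sum."""
    return LatencyBudget(driver_latency, window_acquisition, feature_time, inference_time)


@dataclass(frozen=True)
class DetectionEvent:
    """Classification of one analysis window in a stream."""

    start_s: float
    end_s: float
    probability: float
    label: str
    latency: LatencyBudget

    def to_json(self) -> str:
        d = {
            "start_s": self.start_s,
            "end_s": self.end_s,
            "probability": self.probability,
            "label": self.label,
            "latency_ms": asdict(self.latency) | {"total": self.latency.total},
        }
        return json.dumps(d)


def stream_detect(
    source,
    network: Network,
    cfg: StftConfig,
    stats: NormalizationStats | None = None,
    threshold: float = 0.5,
    driver_latency_ms: float = DEFAULT_DRIVER_LATENCY_MS,
) -> list[DetectionEvent]:
    """Slide over an audio source and classify every analysis window.

    ``source`` is an :class:`AudioClip`, a raw sample array at the
    configured rate, or a WAV path.  One event is emitted per window
    (step ``floor(L/4)``); the first possible detection is one full
    window after stream start.  A stream shorter than ``L`` yields no
    events.  Feature and inference times are measured wall-clock and
    reported in each event's budget — they are hardware-dependent and
    informational only.
    """
    if isinstance(source, (str, Path)):
        clip = read_wav(source)
    elif isinstance(source, AudioClip):
        clip = source
    else:
        clip = AudioClip(samples=np.asarray(source), sample_rate=cfg.sample_rate)
    if clip.sample_rate != cfg.sample_rate:
        raise ValueError(
            f"sample rate {clip.sample_rate} does not match training "
            f"configuration {cfg.sample_rate}"
        )
    extractor = LogMelExtractor(cfg)
    L, step, sr = cfg.window_length, cfg.step, cfg.sample_rate
    acquisition_ms = 1000.0 * L / sr
    x = clip.samples
    events: list[DetectionEvent] = []
    for start in range(0, len(x) - L + 1, step):
        t0 = time.perf_counter()
        spec = extractor(x[start : start + L], stats=stats)
        t1 = time.perf_counter()
        z = network.forward(spec.values[None, :, :], training=False)
        p = float(1.0 / (1.0 + np.exp(-float(z[0]))))
        t2 = time.perf_counter()
        budget = LatencyBudget(
            driver_latency=driver_latency_ms,
            window_acquisition=acquisition_ms,
            feature_time=(t1 - t0) * 1000.0,
            inference_time=(t2 - t1) * 1000.0,
        )
        events.append(
            DetectionEvent(
                start_s=start / sr,
                end_s=(start + L) / sr,
                probability=p,
                label="breakthrough" if p >= threshold else "cortical",
                latency=budget,
            )
        )
    return events
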