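"""Synthetic structure-borne drill-audio generator.

Stands in for (undeposited) cadaver recordings of drilling through the
far cortical layer of a femur until breakthrough into soft tissue.  The
signal model is deliberately minimal but class-separable:

* **cortical drilling**: a quasi-stationary harmonic tone stack (drill
  rotation / gear-mesh vibration with slow frequency jitter and gentle
  amplitude modulation) plus broadband noise, both low-pass filtered to
  mimic soft-tissue damping of the structure-borne path;
* **breakthrough**: an abrupt change at the end of the recording — the
  harmonic energy collapses (the cutting resistance is gone) while a
  loud broadband transient of 100-250 ms bursts in (the drill tearing
  into soft tissue).

Each recording carries exactly one breakthrough by default, mirroring
one event per drill hole, and ends with it; the cortical portion is more
than an order of magnitude longer than the event, which reproduces the
strong class imbalance the detector must cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .audio_io import AudioClip, ManifestEntry, write_manifest, write_wav

__all__ = [
    "SimConfig",
    "LabeledRecording",
    "simulate_drill_recording",
    "simulate_corpus",
    "simulate_recordings",
]


class SimulationConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic drill-audio world.

    Defaults describe a 3 s drill hole recorded at 44.1 kHz: an 650 Hz
    fundamental with 10 harmonics (high-speed surgical drill gear/motor
    vibration), 10 dB harmonic-to-noise ratio, 6 kHz soft-tissue low-pass,
    and one terminal breakthrough of 100-250 ms, giving a worst-case
    cortical:breakthrough duration ratio of (3 - 0.25)/0.25 = 11 > 10.
    """

    sample_rate: int = 44100
    recording_length: float = 3.0
    drill_fundamental: float = 650.0
    fundamental_jitter: float = 0.02
    n_harmonics: int = 10
    noise_snr: float = 10.0
    damping_cutoff: float = 6000.0
    event_duration_range: tuple[float, float] = (100.0, 250.0)
    event_rate: int = 1
    imbalance_target: float = 10.0
    position: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SimulationConfigError("sample_rate must be positive")
        if self.recording_length <= 0:
            raise SimulationConfigError("recording_length must be positive")
        lo, hi = self.event_duration_range
        if not 0 < lo <= hi:
            raise SimulationConfigError("event_duration_range must satisfy 0 < lo <= hi")
        if hi >= self.recording_length * 1000.0:
            raise SimulationConfigError("event duration exceeds recording length")
        if self.drill_fundamental <= 0 or self.n_harmonics < 1:
            raise SimulationConfigError("need a positive fundamental and >= 1 harmonic")
        if self.fundamental_jitter < 0:
            raise SimulationConfigError("fundamental_jitter must be >= 0")
        if self.imbalance_target <= 1:
            raise SimulationConfigError("imbalance_target must exceed 1")
        if self.event_rate < 0:
            raise SimulationConfigError("event_rate must be >= 0")
        if not 0 < self.damping_cutoff < self.sample_rate / 2:
            raise SimulationConfigError("damping_cutoff must lie in (0, Nyquist)")


@dataclass
class LabeledRecording:
    """Synthetic audio plus its ground-truth event intervals."""

    samples: np.ndarray
    sample_rate: int
    events: list[tuple[float, float, str]]
    seed: int
    source_id: str = ""
    position: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("samples must lie in [-1, 1]")
        dur = len(self.samples) / self.sample_rate
        last = 0.0
        for (t0, t1, label) in sorted(self.events):
            if t0 < last - 1e-9 or t1 > dur + 1e-9 or t0 >= t1:
                raise ValueError("event intervals must be sorted, disjoint, in range")
            last = t1

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def as_clip(self) -> AudioClip:
        return AudioClip(
            samples=self.samples,
            sample_rate=self.sample_rate,
            source_id=self.source_id or f"rec{self.seed}",
            position=self.position,
        )


def _lowpass(x: np.ndarray, cutoff: float, sr: int, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff, btype="low", fs=sr, output="sos")
    return sps.sosfilt(sos, x)


def _harmonic_texture(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-stationary harmonic stack with slow jitter and AM."""
    sr = cfg.sample_rate
    t = np.arange(n) / sr
    # slow random-walk frequency jitter, band-limited to a few Hz
    if cfg.fundamental_jitter > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk = _lowpass(walk, 2.0, sr, order=2)
        peak = np.max(np.abs(walk))
        if peak > 0:
            walk = walk / peak
        f0 = cfg.drill_fundamental * (1.0 + cfg.fundamental_jitter * walk)
    else:
        f0 = np.full(n, cfg.drill_fundamental)
    phase0 = np.cumsum(2.0 * np.pi * f0 / sr)
    x = np.zeros(n)
    nyq = sr / 2.0
    for k in range(1, cfg.n_harmonics + 1):
        if k * cfg.drill_fundamental >= 0.95 * nyq:
            break
        amp = 1.0 / k
        x += amp * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))
    # gentle amplitude modulation (feed-pressure variation), ~3 Hz, 10 %
    am = 1.0 + 0.1 * np.sin(2 * np.pi * 3.0 * t + rng.uniform(0, 2 * np.pi))
    return x * am


def simulate_drill_recording(cfg: SimConfig, seed: int) -> LabeledRecording:
    """Synthesize one labeled drill-hole recording.

    The cortical portion is the stationary harmonic+noise texture; with
    ``event_rate=1`` (default) the final ``d`` milliseconds, ``d`` drawn
    uniformly from ``event_duration_range``, are replaced by the
    breakthrough signature (harmonic collapse + broadband burst) and
    recorded as a ``breakthrough`` event interval.  Identical
    ``(cfg, seed)`` give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    sr = cfg.sample_rate
    n = int(round(cfg.recording_length * sr))

    harm = _harmonic_texture(cfg, n, rng)
    harm_rms = np.sqrt(np.mean(harm**2))

    if np.isfinite(cfg.noise_snr):
        noise = rng.standard_normal(n)
        noise = _lowpass(noise, cfg.damping_cutoff, sr)
        noise_rms = np.sqrt(np.mean(noise**2))
        target = harm_rms / 10.0 ** (cfg.noise_snr / 20.0)
        noise *= target / max(noise_rms, 1e-12)
    else:
        noise = np.zeros(n)

    events: list[tuple[float, float, str]] = []
    x = harm + noise

    if cfg.event_rate >= 1:
        lo, hi = cfg.event_duration_range
        dur_s = rng.uniform(lo, hi) / 1000.0
        n_ev = int(round(dur_s * sr))
        i0 = n - n_ev
        t_ev = np.arange(n_ev) / sr

        # harmonic energy collapses over ~10 ms once the far cortex is gone
        drop = 0.15 + 0.85 * np.exp(-t_ev / 0.010)
        x[i0:] = harm[i0:] * drop + noise[i0:]

        # broadband soft-tissue burst: sharp 5 ms attack, mild decay,
        # wider bandwidth than the damped cortical texture
        burst = rng.standard_normal(n_ev)
        burst = _lowpass(burst, min(2.5 * cfg.damping_cutoff, 0.45 * sr), sr)
        burst_rms = np.sqrt(np.mean(burst**2))
        env = (1.0 - np.exp(-t_ev / 0.005)) * np.exp(-t_ev / max(dur_s, 1e-3))
        x[i0:] += burst * env * (3.0 * harm_rms / max(burst_rms, 1e-12))

        events.append((i0 / sr, n / sr, "breakthrough"))

    peak = np.max(np.abs(x), initial=0.0)
    if peak > 0:
        x *= 0.9 / peak  # fixed headroom below full scale; keeps |x| <= 1
    return LabeledRecording(
        samples=x,
        sample_rate=sr,
        events=events,
        seed=int(seed),
        source_id=f"rec{seed:06d}",
        position=cfg.position,
    )


def simulate_corpus(cfg: SimConfig, n_recordings: int, seed: int, out_dir) -> list[ManifestEntry]:
    """Write ``n_recordings`` WAV files plus a ``manifest.csv``.

    The manifest lists every labeled interval — the cortical stretch and
    the breakthrough event of each file — and the aggregate
    cortical:breakthrough duration ratio meets ``cfg.imbalance_target``.
    Returns the manifest entries.
    """
    if n_recordings < 1:
        raise SimulationConfigError("n_recordings must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_recordings) % (2**31)]

    entries: list[ManifestEntry] = []
    for i, child in enumerate(child_seeds):
        rec = simulate_drill_recording(cfg, child)
        rec.source_id = f"hole{i:04d}"
        fname = f"{rec.source_id}.wav"
        write_wav(out_dir / fname, rec.samples, rec.sample_rate)
        cursor = 0.0
        for (t0, t1, label) in rec.events:
            if t0 > cursor:
                entries.append(
                    ManifestEntry(fname, cursor, t0, "cortical", rec.source_id, cfg.position)
                )
            entries.append(ManifestEntry(fname, t0, t1, label, rec.source_id, cfg.position))
            cursor = t1
        if cursor < rec.duration:
            entries.append(
                ManifestEntry(fname, cursor, rec.duration, "cortical", rec.source_id, cfg.position)
            )
    write_manifest(out_dir / "manifest.csv", entries)
    return entries


def simulate_recordings(cfg: SimConfig, n_recordings: int, seed: int) -> list[LabeledRecording]:
    """In-memory corpus: the recordings :func:`simulate_corpus` would write."""
    if n_recordings < 1:
        raise SimulationConfigError("n_recordings must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_recordings) % (2**31)]
    recs = []
    for i, child in enumerate(child_seeds):
        rec = simulate_drill_recording(cfg, child)
        rec.source_id = f"hole{i:04d}"
        recs.append(rec)
    return recs
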