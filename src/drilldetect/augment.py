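"""Waveform augmentation to balance the rare breakthrough class.

Breakthrough events last only 100-250 ms against seconds of cortical
drilling, so the window counts are imbalanced by more than an order of
magnitude.  The minority class is expanded with singly-applied variants:
gain changes (-5, +5 dB), phase-vocoder time stretching (0.5, 0.7, 1.2,
1.5x play rate) and pitch shifting (-3, -1, +1, +3 semitones).  Variants
are generated in repeated passes (variants of variants) until the
majority:minority ratio reaches the target; the final pass subsamples so
the pool is never overshot by a whole pass.  Augmentation is applied to
training folds only — variants carry an ``augmented`` provenance flag so
evaluation code can assert none leaked into a held-out split.

Augmentation operates on waveforms *before* feature extraction: time
stretching changes the clip length, and windows are re-cut afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .audio_io import AudioClip

__all__ = [
    "AugmentationSpec",
    "apply_gain",
    "time_stretch",
    "pitch_shift",
    "variants",
    "balance_training_set",
]


class AugmentationError(ValueError):
    pass


@dataclass(frozen=True)
class AugmentationSpec:
    """The augmentation menu and the balancing target.

    ``target_ratio`` is the maximum allowed majority:minority count ratio
    after balancing (1.0 = fully balanced).
    """

    gains_db: tuple[float, ...] = (-5.0, 5.0)
    stretch_rates: tuple[float, ...] = (0.5, 0.7, 1.2, 1.5)
    pitch_semitones: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gains_db and self.stretch_rates and self.pitch_semitones):
            raise AugmentationError("augmentation lists must be non-empty")
        if any(r <= 0 for r in self.stretch_rates):
            raise AugmentationError("stretch rates must be positive")
        if self.target_ratio < 1.0:
            raise AugmentationError("target_ratio must be >= 1")

    @property
    def n_variants(self) -> int:
        return len(self.gains_db) + len(self.stretch_rates) + len(self.pitch_semitones)


def apply_gain(clip: AudioClip, gain_db: float) -> AudioClip:
    """Scale samples by ``10^(gain_db/20)`` (float domain, may exceed +-1)."""
    factor = 10.0 ** (gain_db / 20.0)
    return clip.with_samples(clip.samples * factor, augmented=True)


# --- phase vocoder -----------------------------------------------------------

_PV_NFFT = 2048
_PV_HOP = 512


def _pv_stft(x: np.ndarray) -> np.ndarray:
    pad = _PV_NFFT // 2
    xp = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n_frames = 1 + len(x) // _PV_HOP
    frames = sliding_window_view(xp, _PV_NFFT)[::_PV_HOP][:n_frames]
    return np.fft.rfft(frames * np.hanning(_PV_NFFT), axis=-1).T


def _pv_istft(S: np.ndarray, length: int) -> np.ndarray:
    win = np.hanning(_PV_NFFT)
    frames = np.fft.irfft(S.T, n=_PV_NFFT, axis=-1) * win
    n_frames = frames.shape[0]
    total = _PV_NFFT + _PV_HOP * (n_frames - 1)
    y = np.zeros(total)
    wsum = np.zeros(total)
    for m in range(n_frames):
        i = m * _PV_HOP
        y[i : i + _PV_NFFT] += frames[m]
        wsum[i : i + _PV_NFFT] += win**2
    y = y / np.maximum(wsum, 1e-8)
    pad = _PV_NFFT // 2
    y = y[pad : pad + length]
    if len(y) < length:
        y = np.pad(y, (0, length - len(y)))
    return y


def _phase_vocoder(S: np.ndarray, rate: float) -> np.ndarray:
    """Resample the STFT time axis by ``rate`` with phase accumulation."""
    n_bins, n_frames = S.shape
    steps = np.arange(0.0, n_frames, rate)
    omega = 2.0 * np.pi * _PV_HOP * np.arange(n_bins) / _PV_NFFT
    out = np.zeros((n_bins, len(steps)), dtype=complex)
    phase = np.angle(S[:, 0])
    Spad = np.concatenate([S, np.zeros((n_bins, 2), dtype=complex)], axis=1)
    for t, step in enumerate(steps):
        i = int(step)
        frac = step - i
        mag = (1.0 - frac) * np.abs(Spad[:, i]) + frac * np.abs(Spad[:, i + 1])
        out[:, t] = mag * np.exp(1j * phase)
        dphi = np.angle(Spad[:, i + 1]) - np.angle(Spad[:, i]) - omega
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase += omega + dphi
    return out


def time_stretch(clip: AudioClip, rate: float) -> AudioClip:
    """Stretch duration by ``1/rate`` at constant pitch (phase vocoder).

    ``rate > 1`` plays faster (shorter), ``rate < 1`` slower (longer); the
    output length is ``round(n / rate)`` exactly.
    """
    if rate <= 0:
        raise AugmentationError("stretch rate must be positive")
    if rate == 1.0:
        return clip.with_samples(clip.samples.copy(), augmented=True)
    n_out = int(round(len(clip.samples) / rate))
    S = _pv_stft(clip.samples)
    S2 = _phase_vocoder(S, rate)
    y = _pv_istft(S2, n_out)
    return clip.with_samples(y, augmented=True)


def pitch_shift(clip: AudioClip, semitones: float) -> AudioClip:
    """Shift pitch by ``semitones`` (factor ``2^(s/12)``) at fixed duration.

    Time-stretch to ``n * r`` samples at constant pitch, then resample
    back to ``n`` samples, which scales all frequencies by ``r``.
    """
    if semitones == 0:
        return clip.with_samples(clip.samples.copy(), augmented=True)
    r = 2.0 ** (semitones / 12.0)
    n = len(clip.samples)
    stretched = time_stretch(clip, rate=1.0 / r)
    y = sps.resample(stretched.samples, n)
    return clip.with_samples(y, augmented=True)


def variants(clip: AudioClip, spec: AugmentationSpec) -> list[AudioClip]:
    """All singly-applied variants of one clip (default: 2 + 4 + 4 = 10)."""
    out = [apply_gain(clip, g) for g in spec.gains_db]
    out += [time_stretch(clip, r) for r in spec.stretch_rates]
    out += [pitch_shift(clip, s) for s in spec.pitch_semitones]
    return out


def balance_training_set(
    clips_by_class: dict[str, list[AudioClip]],
    spec: AugmentationSpec | None = None,
    count_fn=None,
    seed: int = 0,
    max_passes: int = 16,
) -> dict[str, list[AudioClip]]:
    """Expand the minority class until majority:minority <= target_ratio.

    ``count_fn(clip) -> float`` defines how a clip is weighted when
    measuring the ratio (default: 1 per clip; the training pipeline
    passes the number of analysis windows a clip yields).  The majority
    class is returned untouched.  Each pass applies all variants to every
    clip of the current minority pool; the final pass draws a random
    subset (seeded) so the target is met without overshooting by a full
    pass.
    """
    spec = spec or AugmentationSpec()
    if len(clips_by_class) < 2 or any(not v for v in clips_by_class.values()):
        raise AugmentationError("both classes must be present and non-empty")
    if count_fn is None:
        count_fn = lambda clip: 1.0

    totals = {c: sum(count_fn(x) for x in v) for c, v in clips_by_class.items()}
    minority = min(totals, key=totals.get)
    majority = max(totals, key=totals.get)
    if minority == majority:  # tie: nothing to do
        return {c: list(v) for c, v in clips_by_class.items()}

    out = {c: list(v) for c, v in clips_by_class.items()}
    needed = totals[majority] / spec.target_ratio
    rng = np.random.default_rng(seed)
    pool = list(out[minority])
    count = totals[minority]
    for _ in range(max_passes):
        if count >= needed:
            break
        candidates = [v for clip in pool for v in variants(clip, spec)]
        weights = np.array([count_fn(v) for v in candidates])
        if count + weights.sum() <= needed:
            out[minority].extend(candidates)
            count += weights.sum()
            pool = candidates  # next pass augments the new generation
        else:
            order = rng.permutation(len(candidates))
            for idx in order:
                if count >= needed:
                    break
                out[minority].append(candidates[idx])
                count += weights[idx]
            break
    return out
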