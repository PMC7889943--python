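"""Log-mel spectrogram features for drill-audio windows.

An analysis window of ``L`` samples (100/50/25 ms at 44.1 kHz) is turned
into a 256 x 69 log-mel spectrogram: a centered short-time Fourier
transform with Hann window and hop ``H``, squared magnitudes mapped to
decibels, and a 256-band triangular mel filterbank (HTK-style mel scale
``2595 * log10(1 + f/700)``).  The three standard (L, H) pairs
(4410, 64), (2205, 32), (1102, 16) all produce ``1 + floor(L/H) = 69``
time frames, so the network input shape is constant across window
lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

__all__ = [
    "StftConfig",
    "LogMelSpectrogram",
    "NormalizationStats",
    "STANDARD_WINDOWS",
    "hz_to_mel",
    "mel_to_hz",
    "frame_signal",
    "stft_frame",
    "power_to_db",
    "mel_filterbank",
    "compute_logmel",
    "logmel_batch",
    "fit_normalization",
    "apply_normalization",
    "LogMelExtractor",
    "save_features_h5",
    "load_features_h5",
]

#: dB floor applied before the log so silence maps to a finite value.
DB_FLOOR_POWER = 1e-10

#: window-length (ms) -> (L, H) analysis-window / STFT-hop pairs that keep
#: the spectrogram 69 frames wide at 44.1 kHz.
STANDARD_WINDOWS: dict[int, tuple[int, int]] = {
    100: (4410, 64),
    50: (2205, 32),
    25: (1102, 16),
}


class ConfigurationError(ValueError):
    """Raised for invalid feature/analysis configurations."""


@dataclass(frozen=True)
class StftConfig:
    """Framing and spectrogram parameters for one analysis-window length.

    Parameters
    ----------
    window_length : int
        Analysis window ``L`` in samples; one window is classified as a unit.
    hop : int
        STFT hop ``H`` in samples between successive Hann frames inside a
        window.
    n_fft : int
        Hann/FFT length ``N``.  2048 gives 1025 frequency bins, enough to
        support 256 mel filters at 44.1 kHz.
    overlap : float
        Overlap fraction between successive analysis windows when sliding
        over a longer recording (0.75 -> step of ``L/4``).
    sample_rate : int
        Audio sample rate in Hz.
    n_mels : int
        Number of triangular mel bands.
    """

    window_length: int = 4410
    hop: int = 64
    n_fft: int = 2048
    overlap: float = 0.75
    sample_rate: int = 44100
    n_mels: int = 256

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ConfigurationError("window_length must be positive")
        if self.hop <= 0:
            raise ConfigurationError("hop must be positive")
        if self.n_fft < 2:
            raise ConfigurationError("n_fft must be >= 2")
        if not 0.0 <= self.overlap < 1.0:
            raise ConfigurationError("overlap must lie in [0, 1)")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.n_mels < 1:
            raise ConfigurationError("n_mels must be >= 1")
        if self.n_mels > self.n_fft // 2:
            raise ConfigurationError(
                "more mel filters than FFT bins (n_mels > n_fft/2)"
            )

    @classmethod
    def for_window_ms(cls, window_ms: int, **kwargs) -> "StftConfig":
        """Standard configuration for a 100, 50 or 25 ms analysis window."""
        try:
            L, H = STANDARD_WINDOWS[int(window_ms)]
        except KeyError:
            raise ConfigurationError(
                f"window_ms must be one of {sorted(STANDARD_WINDOWS)}, "
                f"got {window_ms}"
            ) from None
        return cls(window_length=L, hop=H, **kwargs)

    @property
    def window_ms(self) -> float:
        """Analysis-window duration in milliseconds (L / sample_rate)."""
        return 1000.0 * self.window_length / self.sample_rate

    @property
    def n_frames(self) -> int:
        """Time frames per analysis window: ``1 + floor(L / H)``."""
        return 1 + self.window_length // self.hop

    @property
    def step(self) -> int:
        """Sliding step between analysis windows: ``floor((1-overlap)*L)``."""
        return int(np.floor((1.0 - self.overlap) * self.window_length))

    @property
    def shape(self) -> tuple[int, int]:
        """(n_mels, n_frames) shape of one spectrogram."""
        return (self.n_mels, self.n_frames)


@dataclass(frozen=True)
class NormalizationStats:
    """Scalar mean/std over every entry of every training spectrogram."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma):
            raise ValueError("normalization stats must be finite")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive (constant training data?)")


@dataclass
class LogMelSpectrogram:
    """A (n_mels, n_frames) log-mel matrix plus the config that produced it."""

    values: np.ndarray
    config: StftConfig = field(default_factory=StftConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("log-mel values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log-mel values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def hz_to_mel(f):
    """HTK mel scale: ``2595 * log10(1 + f / 700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    """Inverse of :func:`hz_to_mel`."""
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def frame_signal(samples: np.ndarray, cfg: StftConfig) -> np.ndarray:
    """Cut a signal into analysis windows of length ``L`` with 75% overlap.

    Returns an array of shape ``(n_windows, L)``; windows start at integer
    multiples of ``cfg.step`` and a trailing partial window is dropped.  A
    signal shorter than ``L`` yields an empty ``(0, L)`` array.
    """
    x = np.asarray(samples, dtype=np.float64).reshape(-1)
    L, step = cfg.window_length, cfg.step
    if len(x) < L:
        return np.empty((0, L))
    if step == 0:
        raise ConfigurationError("overlap too large: window step is zero")
    return sliding_window_view(x, L)[::step].copy()


def _hann(n_fft: int) -> np.ndarray:
    # w(n) = 0.5 * (1 - cos(2 pi n / (N - 1))), the symmetric Hann window
    return np.hanning(n_fft)


def stft_frame(frame: np.ndarray, cfg: StftConfig) -> np.ndarray:
    """Centered STFT of one analysis window.

    The window is zero-padded by ``N/2`` samples on both ends so the
    number of Hann frames is exactly ``1 + floor(L/H)`` for every hop, and
    the result is the complex matrix ``X(k, m)`` with frequency bins
    ``k = 0..N/2`` as rows and time frames ``m`` as columns.
    """
    x = np.asarray(frame, dtype=np.float64).reshape(-1)
    N, H = cfg.n_fft, cfg.hop
    pad = N // 2
    xp = np.concatenate([np.zeros(pad), x, np.zeros(pad)])
    n_frames = 1 + len(x) // H
    frames = sliding_window_view(xp, N)[::H][:n_frames]
    X = np.fft.rfft(frames * _hann(N), axis=-1)
    return X.T


def power_to_db(X: np.ndarray) -> np.ndarray:
    """``10 * log10(max(|X|^2, 1e-10))`` applied entrywise.

    Accepts complex STFT values or real magnitudes; non-negative real
    input that already represents power should instead go through
    ``10*log10`` directly (see :func:`compute_logmel`, which applies the
    mel filterbank to power before taking the log).
    """
    power = np.abs(np.asarray(X)) ** 2
    return 10.0 * np.log10(np.maximum(power, DB_FLOOR_POWER))


def mel_filterbank(cfg: StftConfig) -> np.ndarray:
    """Triangular mel filterbank, shape ``(n_mels, n_fft // 2 + 1)``.

    Peak frequencies are spaced evenly on the mel axis between 0 and
    ``mel(sample_rate / 2)``.  With 256 bands and N = 2048 at 44.1 kHz
    the lowest triangles are narrower than one FFT bin; any filter whose
    sampled weights would vanish entirely is given unit weight at the bin
    nearest its peak so that every row is non-negative with a single
    maximum.
    """
    n_bins = cfg.n_fft // 2 + 1
    fft_freqs = np.linspace(0.0, cfg.sample_rate / 2.0, n_bins)
    mel_pts = np.linspace(0.0, float(hz_to_mel(cfg.sample_rate / 2.0)), cfg.n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)

    fb = np.zeros((cfg.n_mels, n_bins))
    for i in range(cfg.n_mels):
        f_lo, f_c, f_hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - f_lo) / max(f_c - f_lo, 1e-12)
        down = (f_hi - fft_freqs) / max(f_hi - f_c, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        if not fb[i].any():  # triangle fell between two FFT bins
            fb[i, int(np.argmin(np.abs(fft_freqs - f_c)))] = 1.0
    return fb


def compute_logmel(
    frame: np.ndarray,
    cfg: StftConfig,
    stats: NormalizationStats | None = None,
    _fb=None,
) -> LogMelSpectrogram:
    """Full feature pipeline for one analysis window.

    STFT -> squared magnitude -> mel filterbank (applied to power) ->
    decibel scale, yielding a ``(n_mels, 1 + floor(L/H))`` matrix; with the
    standard configurations that is 256 x 69.  If ``stats`` is given the
    result is standardized with the training-pool mean/std.
    """
    X = stft_frame(frame, cfg)
    fb = mel_filterbank(cfg) if _fb is None else _fb
    mel_power = fb @ (np.abs(X) ** 2)
    values = 10.0 * np.log10(np.maximum(mel_power, DB_FLOOR_POWER))
    if stats is not None:
        values = (values - stats.mu) / stats.sigma
    return LogMelSpectrogram(values, cfg)


def logmel_batch(
    windows: np.ndarray,
    cfg: StftConfig,
    stats: NormalizationStats | None = None,
    fb_sparse=None,
    chunk: int = 64,
) -> np.ndarray:
    """Vectorized :func:`compute_logmel` for a stack of equal-length windows.

    Parameters
    ----------
    windows : (n_windows, L) array
    fb_sparse : optional pre-built CSR mel filterbank (from
        :class:`LogMelExtractor`); a dense one is built if omitted.

    Returns
    -------
    (n_windows, n_mels, n_frames) float32 array
    """
    W = np.asarray(windows, dtype=np.float64)
    if W.ndim != 2:
        raise ValueError("windows must be (n_windows, L)")
    n, L = W.shape
    N, H = cfg.n_fft, cfg.hop
    if fb_sparse is None:
        fb_sparse = sparse.csr_matrix(mel_filterbank(cfg))
    pad = N // 2
    win = _hann(N)
    n_frames = 1 + L // H
    out = np.empty((n, cfg.n_mels, n_frames), dtype=np.float32)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        xp = np.pad(W[lo:hi], ((0, 0), (pad, pad)))
        frames = sliding_window_view(xp, N, axis=1)[:, ::H, :][:, :n_frames, :]
        X = np.fft.rfft(frames * win, axis=-1)
        power = (X.real**2 + X.imag**2)  # (b, T, K)
        b = hi - lo
        flat = power.transpose(2, 0, 1).reshape(N // 2 + 1, b * n_frames)
        mel_power = fb_sparse @ flat  # (M, b*T)
        vals = 10.0 * np.log10(np.maximum(mel_power, DB_FLOOR_POWER))
        out[lo:hi] = vals.reshape(cfg.n_mels, b, n_frames).transpose(1, 0, 2)
    if stats is not None:
        out = (out - np.float32(stats.mu)) / np.float32(stats.sigma)
    return out


def fit_normalization(spectrograms) -> NormalizationStats:
    """Scalar mean/std over all entries of all training spectrograms."""
    arrays = [
        s.values if isinstance(s, LogMelSpectrogram) else np.asarray(s)
        for s in spectrograms
    ]
    if len(arrays) < 2 and not (len(arrays) == 1 and arrays[0].ndim == 3):
        raise ValueError("need at least two training spectrograms")
    flat = np.concatenate([a.reshape(-1) for a in arrays]).astype(np.float64)
    mu = float(flat.mean())
    sigma = float(flat.std())
    if sigma <= 0:
        raise ValueError("constant training data: sigma is zero")
    return NormalizationStats(mu=mu, sigma=sigma)


def apply_normalization(spec, stats: NormalizationStats):
    """Standardize a spectrogram (or raw array) with fitted stats."""
    if isinstance(spec, LogMelSpectrogram):
        return LogMelSpectrogram((spec.values - stats.mu) / stats.sigma, spec.config)
    return (np.asarray(spec) - stats.mu) / stats.sigma


class LogMelExtractor:
    """Reusable feature extractor holding a pre-built sparse filterbank.

    Avoids rebuilding the (256, 1025) filterbank per window; the sparse
    matmul makes batch extraction cheap (each triangle touches only a few
    FFT bins).
    """

    def __init__(self, cfg: StftConfig):
        self.cfg = cfg
        self.filterbank = mel_filterbank(cfg)
        self._fb_sparse = sparse.csr_matrix(self.filterbank)

    def __call__(self, window: np.ndarray, stats=None) -> LogMelSpectrogram:
        return compute_logmel(window, self.cfg, stats=stats, _fb=self.filterbank)

    def batch(self, windows: np.ndarray, stats=None) -> np.ndarray:
        return logmel_batch(windows, self.cfg, stats=stats, fb_sparse=self._fb_sparse)

    def from_signal(self, samples: np.ndarray, stats=None) -> np.ndarray:
        """Slide over a long signal and featurize every analysis window."""
        windows = frame_signal(samples, self.cfg)
        if len(windows) == 0:
            warnings.warn("signal shorter than one analysis window")
            return np.empty((0, self.cfg.n_mels, self.cfg.n_frames), dtype=np.float32)
        return self.batch(windows, stats=stats)


def save_features_h5(path, features, labels, source_ids, position="synthetic"):
    """Cache features + metadata in an HDF5 file (one dataset per field)."""
    import h5py

    features = np.asarray(features, dtype=np.float32)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features, compression="gzip")
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        ids = np.asarray(source_ids, dtype="S64")
        f.create_dataset("source_ids", data=ids)
        f.attrs["position"] = position


def load_features_h5(path):
    """Load a feature cache written by :func:`save_features_h5`."""
    import h5py

    with h5py.File(path, "r") as f:
        features = f["features"][...]
        labels = f["labels"][...]
        source_ids = [s.decode() for s in f["source_ids"][...]]
        position = f.attrs.get("position", "synthetic")
    return features, labels, source_ids, position
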