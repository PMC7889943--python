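"""Feature extraction: framing, STFT, mel filterbank, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drilldetect.features import (
    LogMelExtractor,
    NormalizationStats,
    STANDARD_WINDOWS,
    StftConfig,
    apply_normalization,
    compute_logmel,
    fit_normalization,
    frame_signal,
    hz_to_mel,
    load_features_h5,
    logmel_batch,
    mel_filterbank,
    power_to_db,
    save_features_h5,
    stft_frame,
)
from drilldetect.features import ConfigurationError


class TestFraming:
    def test_example_37_frames(self):
        """44100 samples, L=4410, 75% overlap -> 37 windows with step 1102."""
        cfg = StftConfig(window_length=4410, hop=64, overlap=0.75)
        frames = frame_signal(np.zeros(44100), cfg)
        assert cfg.step == 1102
        assert frames.shape == (1 + (44100 - 4410) // 1102, 4410) == (37, 4410)

    def test_exact_length_one_frame(self):
        cfg = StftConfig(window_length=4410, hop=64)
        assert frame_signal(np.zeros(4410), cfg).shape[0] == 1

    def test_no_overlap_two_frames(self):
        cfg = StftConfig(window_length=100, hop=16, overlap=0.0)
        assert frame_signal(np.zeros(200), cfg).shape[0] == 2

    def test_short_signal_empty(self):
        cfg = StftConfig(window_length=4410, hop=64)
        assert frame_signal(np.zeros(100), cfg).shape == (0, 4410)

    @given(
        n=st.integers(min_value=200, max_value=5000),
        L=st.integers(min_value=64, max_value=512),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frame_count_formula(self, n, L, overlap):
        """Window count matches 1 + floor((n - L)/step) for any grid."""
        cfg = StftConfig(window_length=L, hop=16, overlap=overlap, n_fft=128, n_mels=8)
        frames = frame_signal(np.arange(n, dtype=float), cfg)
        step = int(np.floor((1 - overlap) * L))
        expected = 1 + (n - L) // step if n >= L else 0
        assert frames.shape[0] == expected
        # frames really start on the step grid
        if expected > 1:
            assert frames[1, 0] == step


class TestStft:
    def test_zero_frame_zero_magnitudes(self, stft_cfg_100ms):
        X = stft_frame(np.zeros(4410), stft_cfg_100ms)
        assert np.allclose(np.abs(X), 0.0)

    @pytest.mark.parametrize("wms", [100, 50, 25])
    def test_69_time_frames(self, wms):
        """All three (L, H) pairs give 69 frames under the centered STFT."""
        cfg = StftConfig.for_window_ms(wms)
        X = stft_frame(np.ones(cfg.window_length), cfg)
        assert X.shape == (cfg.n_fft // 2 + 1, 69)

    def test_pure_tone_peak_bin(self):
        """1 kHz sine at 44.1 kHz, N=2048 -> peak at bin round(1000*2048/44100)=46."""
        cfg = StftConfig.for_window_ms(100)
        t = np.arange(cfg.window_length) / cfg.sample_rate
        X = np.abs(stft_frame(np.sin(2 * np.pi * 1000 * t), cfg))
        # interior frames see the full tone (edge frames are mostly padding)
        for m in range(20, 50):
            assert np.argmax(X[:, m]) == 46

    def test_oracle_naive_dft(self, rng):
        """Framed-FFT magnitudes match a direct evaluation of the DFT sum."""
        cfg = StftConfig.for_window_ms(25)  # L=1102, H=16
        frame = rng.standard_normal(cfg.window_length)
        X = stft_frame(frame, cfg)
        N, H = cfg.n_fft, cfg.hop
        pad = N // 2
        xp = np.concatenate([np.zeros(pad), frame, np.zeros(pad)])
        w = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(N) / (N - 1)))
        n_idx = np.arange(N)
        k_idx = np.arange(N // 2 + 1)
        dft = np.exp(-2j * np.pi * np.outer(n_idx, k_idx) / N)
        for m in [0, 17, 42, X.shape[1] - 1]:
            seg = xp[m * H : m * H + N] * w
            naive = seg @ dft
            denom = np.maximum(np.abs(naive), 1e-12)
            assert np.max(np.abs(np.abs(X[:, m]) - np.abs(naive)) / denom) < 1e-6


class TestDecibel:
    @pytest.mark.parametrize(
        "mag,expected", [(1.0, 0.0), (10.0, 20.0), (0.0, -100.0)]
    )
    def test_reference_values(self, mag, expected):
        assert power_to_db(np.array([mag]))[0] == pytest.approx(expected)


class TestMelFilterbank:
    def test_mel_scale_values(self):
        assert hz_to_mel(0.0) == 0.0
        assert hz_to_mel(700.0) == pytest.approx(2595.0 * np.log10(2.0), abs=1e-9)

    def test_mel_strictly_increasing(self):
        f = np.linspace(0, 22050, 2000)
        assert np.all(np.diff(hz_to_mel(f)) > 0)

    def test_shape_and_positivity(self, stft_cfg_100ms):
        fb = mel_filterbank(stft_cfg_100ms)
        assert fb.shape == (256, 1025)
        assert np.all(fb >= 0)
        # every filter has support and a single maximal value
        for row in fb:
            assert row.max() > 0
            assert np.count_nonzero(row == row.max()) == 1

    def test_peaks_evenly_spaced_on_mel_axis(self, stft_cfg_100ms):
        cfg = stft_cfg_100ms
        mel_pts = np.linspace(0, hz_to_mel(cfg.sample_rate / 2), cfg.n_mels + 2)
        diffs = np.diff(mel_pts)
        assert np.allclose(diffs, diffs[0])

    def test_too_many_filters_rejected(self):
        with pytest.raises(ConfigurationError):
            StftConfig(n_fft=256, n_mels=256)


class TestLogMel:
    @pytest.mark.parametrize("wms", [100, 50, 25])
    def test_shape_256x69_all_configs(self, wms, rng):
        cfg = StftConfig.for_window_ms(wms)
        spec = compute_logmel(rng.standard_normal(cfg.window_length), cfg)
        assert spec.shape == (256, 69)

    def test_zero_frame_at_floor(self, stft_cfg_100ms):
        spec = compute_logmel(np.zeros(4410), stft_cfg_100ms)
        assert np.allclose(spec.values, -100.0)

    def test_gain_shifts_by_20log10(self, stft_cfg_100ms, rng):
        """Scaling the waveform by g adds exactly 20*log10(g) dB everywhere."""
        frame = rng.standard_normal(4410)
        a = compute_logmel(frame, stft_cfg_100ms).values
        b = compute_logmel(10.0 * frame, stft_cfg_100ms).values
        mask = a > -99.0  # away from the dB floor
        assert mask.all()
        assert np.allclose(b - a, 20.0, atol=1e-8)

    def test_batch_matches_single(self, stft_cfg_100ms, rng):
        windows = rng.standard_normal((3, 4410))
        batch = logmel_batch(windows, stft_cfg_100ms)
        for i in range(3):
            single = compute_logmel(windows[i], stft_cfg_100ms).values
            assert np.allclose(batch[i], single, atol=1e-4)


class TestNormalization:
    def test_known_pool(self):
        stats = fit_normalization([np.array([[0.0]]), np.array([[2.0]])])
        assert stats.mu == 1.0 and stats.sigma == 1.0
        assert apply_normalization(np.array([[0.0]]), stats)[0, 0] == -1.0

    def test_pooled_mean_zero_std_one(self, stft_cfg_100ms, rng):
        specs = [
            compute_logmel(rng.standard_normal(4410), stft_cfg_100ms) for _ in range(4)
        ]
        stats = fit_normalization(specs)
        pooled = np.concatenate(
            [apply_normalization(s, stats).values.ravel() for s in specs]
        )
        assert abs(pooled.mean()) < 1e-6
        assert abs(pooled.std() - 1.0) < 1e-6

    def test_refit_idempotent(self, stft_cfg_100ms, rng):
        specs = [
            compute_logmel(rng.standard_normal(4410), stft_cfg_100ms) for _ in range(4)
        ]
        stats = fit_normalization(specs)
        normed = [apply_normalization(s, stats) for s in specs]
        stats2 = fit_normalization(normed)
        assert abs(stats2.mu) < 1e-9
        assert abs(stats2.sigma - 1.0) < 1e-9

    def test_no_leakage_on_held_out(self, stft_cfg_100ms, rng):
        """Stats fitted on one pool do not standardize a different pool."""
        train = [compute_logmel(rng.standard_normal(4410), stft_cfg_100ms) for _ in range(3)]
        test = [compute_logmel(5 + rng.standard_normal(4410), stft_cfg_100ms) for _ in range(3)]
        stats = fit_normalization(train)
        test_mean = np.mean([apply_normalization(s, stats).values.mean() for s in test])
        assert abs(test_mean) > 0.1

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="sigma|constant"):
            fit_normalization([np.ones((2, 2)), np.ones((2, 2))])

    def test_sigma_zero_invalid(self):
        with pytest.raises(ValueError):
            NormalizationStats(mu=0.0, sigma=0.0)


def test_h5_cache_roundtrip(tmp_path, rng):
    X = rng.standard_normal((4, 8, 9)).astype(np.float32)
    y = [0, 1, 0, 1]
    ids = ["a", "a", "b", "b"]
    save_features_h5(tmp_path / "cache.h5", X, y, ids, position="synthetic")
    X2, y2, ids2, pos = load_features_h5(tmp_path / "cache.h5")
    assert np.array_equal(X, X2) and list(y2) == y and ids2 == ids
    assert pos == "synthetic"
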