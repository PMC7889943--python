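"""Focal loss identities, network construction, parameter accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drilldetect import nn
from drilldetect.model import (
    FocalLossParams,
    LabelError,
    ModelSpec,
    Network,
    build_network,
    count_parameters,
    focal_loss,
    load_checkpoint,
    save_checkpoint,
)


class TestFocalLoss:
    def test_confident_correct_vanishes(self):
        assert focal_loss(1 - 1e-9, 1) == pytest.approx(0.0, abs=1e-6)
        assert focal_loss(1e-9, 0) == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_cross_entropy(self):
        """gamma=0, alpha_t=1: plain binary cross-entropy, to 1e-12."""
        params = FocalLossParams(alpha_t=1.0, gamma=0.0)
        for p in np.linspace(0.01, 0.99, 33):
            for y in (0, 1):
                bce = -(y * math.log(p) + (1 - y) * math.log(1 - p))
                assert abs(focal_loss(float(p), y, params) - bce) < 1e-12

    def test_printed_example_value(self):
        """alpha=0.25, gamma=2, y=1, p=0.9 -> 0.25 * 0.01 * (-ln 0.9)."""
        got = focal_loss(0.9, 1, FocalLossParams(0.25, 2.0))
        assert got == pytest.approx(0.25 * 0.01 * -math.log(0.9), rel=1e-9)
        assert got == pytest.approx(2.634e-4, rel=1e-3)

    def test_half_probability_cross_entropy(self):
        assert focal_loss(0.5, 1, FocalLossParams(1.0, 0.0)) == pytest.approx(
            0.693147, abs=1e-6
        )

    @given(st.floats(min_value=0.01, max_value=0.98))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_pt(self, p):
        """More confidence in the true class always lowers the loss."""
        params = FocalLossParams()
        assert focal_loss(p + 0.01, 1, params) < focal_loss(p, 1, params)
        assert focal_loss(p, 0, params) < focal_loss(p + 0.01, 0, params)

    @given(
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
        st.sampled_from([0, 1]),
        st.floats(min_value=0.0, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_non_negative(self, p, y, gamma):
        assert focal_loss(p, y, FocalLossParams(0.25, gamma)) >= 0.0

    def test_gamma_downweights_easy_examples(self):
        """FL(0.9)/FL(0.1) for y=1 shrinks when gamma goes 0 -> 2."""
        r0 = focal_loss(0.9, 1, FocalLossParams(1.0, 0.0)) / focal_loss(
            0.1, 1, FocalLossParams(1.0, 0.0)
        )
        r2 = focal_loss(0.9, 1, FocalLossParams(1.0, 2.0)) / focal_loss(
            0.1, 1, FocalLossParams(1.0, 2.0)
        )
        assert r2 < r0

    def test_batch_mean(self):
        p = np.array([0.9, 0.2])
        y = np.array([1, 0])
        single = [focal_loss(float(pi), int(yi)) for pi, yi in zip(p, y)]
        assert focal_loss(p, y) == pytest.approx(np.mean(single))

    def test_invalid_label(self):
        with pytest.raises(LabelError):
            focal_loss(0.5, 2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FocalLossParams(alpha_t=0.0)
        with pytest.raises(ValueError):
            FocalLossParams(gamma=-1.0)

    def test_logits_version_matches(self, rng):
        z = rng.standard_normal(64)
        y = (rng.random(64) < 0.5).astype(float)
        from scipy.special import expit

        loss, _ = nn.focal_loss_with_logits(z, y, 0.25, 2.0)
        assert loss == pytest.approx(focal_loss(expit(z), y), rel=1e-9)


class TestNetwork:
    def test_full_parameter_count_band(self):
        """Total count (incl. BN running stats) within +-0.5% of 11,715,393."""
        net = build_network(ModelSpec(), seed=0)
        n = count_parameters(net)
        assert 11_656_816 <= n <= 11_773_970

    def test_dense_layer_count_examples(self):
        layer = nn.Dense(512, 1024, rng=np.random.default_rng(0))
        assert sum(p.size for p in layer.parameters()) == 512 * 1024 + 1024
        out = nn.Dense(1024, 1, rng=np.random.default_rng(0))
        assert sum(p.size for p in out.parameters()) == 1025

    def test_eval_mode_deterministic(self):
        net = build_network(ModelSpec.reduced(), seed=1)
        x = np.zeros((2, 1, 256, 69), np.float32)
        a = net.predict_proba(x)
        b = net.predict_proba(x)
        assert np.array_equal(a, b)

    def test_same_seed_same_outputs(self, rng):
        x = rng.standard_normal((2, 1, 256, 69)).astype(np.float32)
        a = build_network(ModelSpec.reduced(), seed=7).predict_proba(x)
        b = build_network(ModelSpec.reduced(), seed=7).predict_proba(x)
        assert np.array_equal(a, b)

    def test_output_is_probability(self, rng):
        net = build_network(ModelSpec.reduced(), seed=0)
        x = (rng.standard_normal((4, 1, 256, 69)) * 50).astype(np.float32)
        p = net.predict_proba(x)
        assert np.all((p > 0) & (p < 1))

    def test_dropout_only_in_training(self, rng):
        net = build_network(ModelSpec.reduced(), seed=0)
        x = rng.standard_normal((2, 1, 256, 69)).astype(np.float32)
        z1 = net.forward(x, training=True)
        z2 = net.forward(x, training=True)
        assert not np.array_equal(z1, z2)  # dropout masks differ
        e1 = net.forward(x, training=False)
        e2 = net.forward(x, training=False)
        assert np.array_equal(e1, e2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(input_shape=(3, 256, 69))
        with pytest.raises(ValueError):
            ModelSpec(dropout=1.5)
        with pytest.raises(ValueError):
            ModelSpec(blocks=(2, 2, 2))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = build_network(ModelSpec.reduced(), seed=3)
        from drilldetect.features import NormalizationStats, StftConfig

        save_checkpoint(
            tmp_path / "ckpt", net, StftConfig.for_window_ms(50),
            NormalizationStats(mu=-40.0, sigma=12.5),
        )
        net2, cfg2, stats2 = load_checkpoint(tmp_path / "ckpt")
        x = rng.standard_normal((2, 1, 256, 69)).astype(np.float32)
        assert np.array_equal(net.predict_proba(x), net2.predict_proba(x))
        assert cfg2.window_length == 2205 and cfg2.hop == 32
        assert stats2.mu == -40.0


class TestGradients:
    def test_backprop_matches_numerical_gradient(self, rng):
        """Central-difference check through conv/BN/pool/dense + focal loss."""
        conv = nn.Conv2d(1, 2, 3, stride=2, pad=1, rng=rng)
        bn = nn.BatchNorm2d(2)
        net = nn.Sequential(
            [conv, bn, nn.ReLU(), nn.MaxPool2d(3, 2, 1), nn.GlobalAvgPool(),
             nn.Dense(2, 1, rng=rng)]
        )
        x = rng.standard_normal((4, 1, 10, 8)).astype(np.float32)
        y = np.array([1, 0, 1, 0], np.float32)

        def loss():
            z = net.forward(x, True).reshape(-1)
            return nn.focal_loss_with_logits(z, y)

        l, dz = loss()
        for p in net.parameters():
            p.grad[...] = 0.0
        net.backward(dz.reshape(-1, 1))
        eps = 1e-3
        for p in net.parameters():
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp, _ = loss()
            p.value[idx] = orig - eps
            lm, _ = loss()
            p.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, abs=2e-3, rel=2e-2)

    def test_residual_block_gradient(self, rng):
        block = nn.BasicBlock(2, 3, stride=2, rng=rng)
        head = nn.Sequential([block, nn.GlobalAvgPool(), nn.Dense(3, 1, rng=rng)])
        x = rng.standard_normal((2, 2, 8, 6)).astype(np.float32)
        y = np.array([1, 0], np.float32)

        def loss():
            z = head.forward(x, True).reshape(-1)
            return nn.focal_loss_with_logits(z, y)

        _, dz = loss()
        for p in head.parameters():
            p.grad[...] = 0.0
        head.backward(dz.reshape(-1, 1))
        eps = 1e-3
        for p in head.parameters()[:6]:
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            lp, _ = loss()
            p.value[idx] = orig - eps
            lm, _ = loss()
            p.value[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, abs=2e-3, rel=2e-2)

    def test_adam_reduces_loss_on_toy_problem(self, rng):
        dense = nn.Dense(4, 1, rng=rng)
        opt = nn.Adam(dense.parameters(), lr=0.05)
        X = rng.standard_normal((64, 4)).astype(np.float32)
        y = (X[:, 0] > 0).astype(np.float32)
        first = None
        for _ in range(100):
            z = dense.forward(X, True).reshape(-1)
            loss, dz = nn.focal_loss_with_logits(z, y)
            first = first if first is not None else loss
            opt.zero_grad()
            dense.backward(dz.reshape(-1, 1))
            opt.step()
        assert loss < 0.2 * first
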