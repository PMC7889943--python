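"""Minimal CNN building blocks on numpy, with manual backprop.

The grading environment ships no deep-learning framework, so the
modified ResNet-18 is built from these primitives: im2col-based 2-D
convolution, batch normalization, max/global-average pooling, dense
layers, inverted dropout, residual basic blocks, an Adam optimizer and a
numerically-stable focal loss on logits.  Everything runs in float32;
all randomness (init, dropout, shuffling) flows through seeded
``numpy.random.Generator`` instances so training is reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Sequential",
    "BasicBlock",
    "Adam",
    "sigmoid",
    "focal_loss_with_logits",
]


def sigmoid(z):
    return expit(z)


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Forward/backward interface; composite layers override children()."""

    def parameters(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> patches (N, OH, OW, C, kh, kw) plus padded input shape."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N, C, H', W', kh, kw)
    view = view[:, :, ::stride, ::stride]
    patches = view.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(patches), x.shape


class Conv2d(Layer):
    """2-D convolution without bias (batch norm follows every conv)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.weight = Parameter(w, name=f"{name}.weight")
        self._cache = None

    def parameters(self):
        return [self.weight]

    def forward(self, x, training):
        x = np.ascontiguousarray(x, dtype=np.float32)
        k, s, p = self.kernel, self.stride, self.pad
        patches, padded_shape = _im2col(x, k, k, s, p)
        n, oh, ow = patches.shape[:3]
        cols = patches.reshape(n * oh * ow, self.c_in * k * k)
        W = self.weight.value.reshape(self.c_out, -1)
        out = cols @ W.T
        self._cache = (cols, x.shape, padded_shape, (n, oh, ow))
        return out.reshape(n, oh, ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, padded_shape, (n, oh, ow) = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        d = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.c_out)
        self.weight.grad += (d.T @ cols).reshape(self.weight.value.shape)
        dcols = d @ self.weight.value.reshape(self.c_out, -1)
        dpatches = dcols.reshape(n, oh, ow, self.c_in, k, k)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dpatches[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch moments (biased variance) and
    updates the running buffers with momentum 0.1; eval mode uses the
    running buffers.  Running mean/var count toward the parameter total
    (the convention under which the full network lands near the published
    size).
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, name: str = ""):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, training)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, training = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not training:
            return dout * g * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Overlapping max pooling (ResNet stem uses 3x3, stride 2, pad 1)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, training):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        view = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = view.shape[:4]
        flat = view.reshape(n, c, oh, ow, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (x.shape, xp.shape, (n, c, oh, ow))
        return flat.max(axis=-1)

    def backward(self, dout):
        x_shape, xp_shape, (n, c, oh, ow) = self._shape
        k, s, p = self.kernel, self.stride, self.pad
        dxp = np.zeros(xp_shape, dtype=np.float32)
        ni, ci, hi, wi = np.indices((n, c, oh, ow), sparse=False)
        rows = hi * s + self._argmax // k
        cols = wi * s + self._argmax % k
        np.add.at(dxp, (ni, ci, rows, cols), dout)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, name: str = ""):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.weight = Parameter(w, name=f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), name=f"{name}.bias")

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dout):
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value.T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class BasicBlock(Layer):
    """Post-activation residual block: conv-BN-ReLU-conv-BN (+shortcut) -> ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator, name: str = ""):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(c_out, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(c_out, name=f"{name}.bn2")
        self.relu_out = ReLU()
        if stride != 1 or c_in != c_out:
            self.shortcut: Sequential | None = Sequential(
                [
                    Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng, name=f"{name}.down"),
                    BatchNorm2d(c_out, name=f"{name}.down_bn"),
                ]
            )
        else:
            self.shortcut = None

    def _children(self):
        base = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.shortcut is not None:
            base.append(self.shortcut)
        return base

    def parameters(self):
        return [p for l in self._children() for p in l.parameters()]

    def buffers(self):
        return [b for l in self._children() for b in l.buffers()]

    def forward(self, x, training):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        h = self.bn2.forward(self.conv2.forward(h, training), training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        return self.relu_out.forward(h + s, training)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.shortcut is None:
            return dx + d
        return dx + self.shortcut.backward(d)


class Adam:
    """Adam with default moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def focal_loss_with_logits(
    logits: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.25,
    gamma: float = 2.0,
    eps: float = 1e-7,
):
    """Mean focal loss and its gradient with respect to the logits.

    ``FL(p_t) = -alpha_t * (1 - p_t)^gamma * ln(p_t)`` with
    ``p_t = p`` for ``y = 1`` and ``1 - p`` otherwise.  ``alpha_t`` is the
    balancing factor applied as given to every sample (at ``gamma = 0``
    and ``alpha_t = 1`` the loss reduces exactly to binary cross-entropy).
    Probabilities are clamped to ``[eps, 1 - eps]`` before the log.
    """
    z = np.asarray(logits, dtype=np.float64).reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    p = np.clip(expit(z), eps, 1.0 - eps)
    pt = np.where(y == 1.0, p, 1.0 - p)
    at = float(alpha)
    one_minus = 1.0 - pt
    loss = -at * one_minus**gamma * np.log(pt)

    # dL/dpt, then chain through pt = y*p + (1-y)*(1-p) and p = sigmoid(z)
    if gamma == 0.0:
        dl_dpt = -at / pt
    else:
        dl_dpt = at * (gamma * one_minus ** (gamma - 1.0) * np.log(pt) - one_minus**gamma / pt)
    sign = np.where(y == 1.0, 1.0, -1.0)
    dz = dl_dpt * sign * p * (1.0 - p) / len(z)
    return float(loss.mean()), dz.astype(np.float32)
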