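"""Minimal NumPy layers with explicit forward/backward passes.

Voxel tensors are channels-last: (batch, depth, height, width, channels).
Only what the 3D DenseNet/ResNet classifiers need is implemented: 3x3x3
same-padding convolution, dropout, batch normalization, ReLU, 2x2x2 average
pooling, global max pooling, a dense head, and softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    training = False

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(x: np.ndarray) -> np.ndarray:
    """(N, D, H, W, C) -> zero-padded sliding 3x3x3 windows
    (N, D, H, W, 3, 3, 3, C)."""
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    return sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3)).transpose(
        0, 1, 2, 3, 5, 6, 7, 4)


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same padding (or 1x1x1 for kernel=1)."""

    def __init__(self, in_channels: int, filters: int, rng: np.random.Generator,
                 kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.kernel = kernel
        fan_in = kernel ** 3 * in_channels
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        self.w = Parameter(rng.normal(
            0.0, scale, size=(kernel, kernel, kernel, in_channels, filters)))
        self.b = Parameter(np.zeros(filters))
        self._x = None

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        if self.kernel == 1:
            y = np.einsum("ndhwc,cf->ndhwf", x, self.w.value[0, 0, 0])
        else:
            win = _windows(x)
            y = np.einsum("ndhwijkc,ijkcf->ndhwf", win, self.w.value,
                          optimize=True)
        return y + self.b.value

    def backward(self, dy):
        x = self._x
        self.b.grad += dy.sum(axis=(0, 1, 2, 3))
        if self.kernel == 1:
            self.w.grad[0, 0, 0] += np.einsum("ndhwc,ndhwf->cf", x, dy)
            return np.einsum("ndhwf,cf->ndhwc", dy, self.w.value[0, 0, 0])
        win = _windows(x)
        self.w.grad += np.einsum("ndhwijkc,ndhwf->ijkcf", win, dy,
                                 optimize=True)
        wf = self.w.value[::-1, ::-1, ::-1]
        dwin = _windows(dy)
        return np.einsum("ndhwijkf,ijkcf->ndhwc", dwin, wf, optimize=True)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        axes = (0, 1, 2, 3)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, shape = self._cache
        m = np.prod([shape[i] for i in range(4)])
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 1, 2, 3))
        if not self.training:
            return dy * self.gamma.value * inv
        dxhat = dy * self.gamma.value
        return (inv / m) * (m * dxhat
                            - dxhat.sum(axis=(0, 1, 2, 3))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2, 3)))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool3D(Layer):
    """Non-overlapping 2x2x2 average pooling."""

    def forward(self, x):
        n, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        self._shape = x.shape
        return x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).mean(
            axis=(2, 4, 6))

    def backward(self, dy):
        n, d, h, w, c = self._shape
        dy = dy[:, :, None, :, None, :, None, :] / 8.0
        return np.broadcast_to(
            dy, (n, d // 2, 2, h // 2, 2, w // 2, 2, c)).reshape(self._shape)


class GlobalMaxPool3D(Layer):
    """(N, D, H, W, C) -> (N, C) by spatial max."""

    def forward(self, x):
        n, d, h, w, c = x.shape
        flat = x.reshape(n, d * h * w, c)
        self._argmax = flat.argmax(axis=1)
        self._shape = x.shape
        return flat.max(axis=1)

    def backward(self, dy):
        n, d, h, w, c = self._shape
        dx = np.zeros((n, d * h * w, c), dtype=dy.dtype)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ni, self._argmax, ci] = dy
        return dx.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, scale,
                                      size=(in_features, out_features)))
        self.b = Parameter(np.zeros(out_features))

    def parameters(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.maximum(p, 1e-12))).sum() / n)
    return loss, (p - onehot) / n
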