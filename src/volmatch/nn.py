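"""Minimal 3D neural-network layers with explicit backpropagation.

Just enough machinery for a small volumetric CNN: valid 3D convolution,
non-overlapping max pooling with floor division, per-element PReLU,
dense layers, inverted dropout, and a sequential container.  Arrays are
laid out ``(batch, channels, x, y, z)``.  Gradients accumulate into
``Param.grad`` during :meth:`Layer.backward`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "MaxPool3D", "Conv3D", "PReLU", "Flatten",
    "Dense", "Dropout", "Sequential", "bce_with_logits", "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` vs labels ``y`` and dL/dz."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    # log(1 + e^z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / len(z)
    return loss, grad


class Param:
    """A trainable array with its gradient buffer."""

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MaxPool3D(Layer):
    """Non-overlapping max pooling (stride = size, trailing voxels dropped)."""

    def __init__(self, size: int):
        self.size = int(size)

    def forward(self, x, training=False):
        s = self.size
        b, c, nx, ny, nz = x.shape
        ox, oy, oz = nx // s, ny // s, nz // s
        if min(ox, oy, oz) == 0:
            raise ValueError(f"max-pool {s} collapses input of shape {x.shape}")
        xc = x[:, :, :ox * s, :oy * s, :oz * s]
        blocks = xc.reshape(b, c, ox, s, oy, s, oz, s)
        out = blocks.max(axis=(3, 5, 7))
        self._cache = (x.shape, blocks, out)
        return out

    def backward(self, grad):
        s = self.size
        in_shape, blocks, out = self._cache
        mx = out[:, :, :, None, :, None, :, None]
        mask = blocks == mx
        counts = mask.sum(axis=(3, 5, 7), keepdims=True)
        g = mask * (grad[:, :, :, None, :, None, :, None] / counts)
        b, c, ox, _, oy, _, oz, _ = blocks.shape
        dx = np.zeros(in_shape, dtype=np.float64)
        dx[:, :, :ox * s, :oy * s, :oz * s] = g.reshape(
            b, c, ox * s, oy * s, oz * s)
        return dx


class Conv3D(Layer):
    """Valid (no-padding, stride-1) 3D convolution."""

    def __init__(self, in_channels: int, n_filters: int, kernel: int,
                 rng: np.random.Generator):
        k = int(kernel)
        fan_in = in_channels * k ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(n_filters, in_channels, k, k, k))
        self.kernel = k
        self.w = Param("conv.w", w)
        self.b = Param("conv.b", np.zeros(n_filters))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        k = self.kernel
        if min(x.shape[2:]) < k:
            raise ValueError(
                f"conv kernel {k} larger than input extent {x.shape[2:]}")
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        out = np.einsum("bcxyzijk,fcijk->bfxyz", win, self.w.value,
                        optimize=True)
        out += self.b.value[None, :, None, None, None]
        self._x = x
        return out

    def backward(self, grad):
        k = self.kernel
        win = sliding_window_view(self._x, (k, k, k), axis=(2, 3, 4))
        self.w.grad += np.einsum("bcxyzijk,bfxyz->fcijk", win, grad,
                                 optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        pad = [(0, 0), (0, 0)] + [(k - 1, k - 1)] * 3
        gp = np.pad(grad, pad)
        gw = sliding_window_view(gp, (k, k, k), axis=(2, 3, 4))
        w_flip = self.w.value[:, :, ::-1, ::-1, ::-1]
        return np.einsum("bfxyzijk,fcijk->bcxyz", gw, w_flip, optimize=True)


class PReLU(Layer):
    """Parametrized ReLU with one learnable slope per tensor element."""

    def __init__(self, feature_shape: tuple[int, ...], init: float = 0.25):
        self.alpha = Param("prelu.alpha",
                           np.full(feature_shape, init, dtype=np.float64))

    def params(self):
        return [self.alpha]

    def forward(self, x, training=False):
        pos = x > 0
        self._cache = (x, pos)
        return np.where(pos, x, self.alpha.value * x)

    def backward(self, grad):
        x, pos = self._cache
        self.alpha.grad += np.where(pos, 0.0, grad * x).sum(axis=0)
        return grad * np.where(pos, 1.0, self.alpha.value)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Param("dense.w", rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param("dense.b", np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Dropout(Layer):
    """Inverted dropout: active only when ``training=True``."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v
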