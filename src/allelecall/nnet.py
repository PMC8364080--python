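"""Minimal 1-D convolutional network engine on numpy.

Implements exactly the pieces the caller's architecture needs: weight-
normalized 1-D convolutions and affine layers, rectified linear units,
residual pairs, global average pooling, and a sigmoid head, each with a
hand-written backward pass.  Weight normalization reparameterizes a
weight tensor as w = g * v / ||v|| (norm per output unit), so layer
statistics never depend on batch composition — important here because
sites contribute batches of wildly varying size (read depth, candidate
count).

Shapes follow the (N, C, L) convention: batch, channels, positions.
Convolutions are 'same'-padded, stride 1.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def parameters(self) -> Dict[str, Parameter]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding windows over the last axis after 'same' zero padding.

    (N, C, L) -> (N, C, L, k)
    """
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


class WNConv1d(Layer):
    """Weight-normalized 1-D convolution, stride 1, 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel
        v = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel))
        self.v = Parameter(v)
        self.g = Parameter(np.ones(out_channels))
        self.b = Parameter(np.zeros(out_channels))
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> Dict[str, Parameter]:
        return {"v": self.v, "g": self.g, "b": self.b}

    def _weight(self) -> np.ndarray:
        norm = np.sqrt((self.v.value**2).sum(axis=(1, 2), keepdims=True)) + 1e-12
        return self.g.value[:, None, None] * self.v.value / norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        w = self._weight()
        win = _windows(x, self.kernel)  # (N, Cin, L, K)
        y = np.einsum("nclk,ock->nol", win, w, optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        w = self._weight()
        win = _windows(x, self.kernel)
        dw = np.einsum("nclk,nol->ock", win, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        # chain rule through w = g * v / ||v||
        norm = np.sqrt((self.v.value**2).sum(axis=(1, 2), keepdims=True)) + 1e-12
        u = self.v.value / norm
        dg = (dw * u).sum(axis=(1, 2))
        self.g.grad += dg
        self.v.grad += (self.g.value[:, None, None] / norm) * (dw - u * dg[:, None, None])
        # dx: correlate grad with the flipped kernel, channels transposed
        wt = np.flip(w, axis=2).transpose(1, 0, 2)  # (Cin, Cout, K)
        gwin = _windows(grad, self.kernel)  # (N, Cout, L, K)
        return np.einsum("nolk,cok->ncl", gwin, wt, optimize=True)


class WNLinear(Layer):
    """Weight-normalized affine layer on (N, F) inputs."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        v = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.v = Parameter(v)
        self.g = Parameter(np.ones(out_features))
        self.b = Parameter(np.zeros(out_features))
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> Dict[str, Parameter]:
        return {"v": self.v, "g": self.g, "b": self.b}

    def _weight(self) -> np.ndarray:
        norm = np.sqrt((self.v.value**2).sum(axis=1, keepdims=True)) + 1e-12
        return self.g.value[:, None] * self.v.value / norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self._weight().T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        dw = grad.T @ x
        self.b.grad += grad.sum(axis=0)
        norm = np.sqrt((self.v.value**2).sum(axis=1, keepdims=True)) + 1e-12
        u = self.v.value / norm
        dg = (dw * u).sum(axis=1)
        self.g.grad += dg
        self.v.grad += (self.g.value[:, None] / norm) * (dw - u * dg[:, None])
        return grad @ self._weight()


class ReLU(Layer):
    def __init__(self):
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class ResidualPair(Layer):
    """Skip connection over a pair of convolutional layers.

    y = relu( conv2(relu(conv1(x))) + x ), channel-preserving.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = WNConv1d(channels, channels, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = WNConv1d(channels, channels, kernel, rng)
        self.relu_out = ReLU()

    def parameters(self) -> Dict[str, Parameter]:
        out = {}
        for name, p in self.conv1.parameters().items():
            out[f"conv1.{name}"] = p
        for name, p in self.conv2.parameters().items():
            out[f"conv2.{name}"] = p
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(h + x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx + g


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) mean over positions."""

    def __init__(self):
        self._length: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers: List[Layer] = list(layers)

    def parameters(self) -> Dict[str, Parameter]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.parameters().items():
                out[f"{i}.{name}"] = p
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def count_parameters(module: Layer) -> int:
    """Trainable scalar count, weight-norm stored as direction + gain."""
    return sum(int(p.value.size) for p in module.parameters().values())


class Adam:
    """Adaptive-moment optimizer over a parameter dict."""

    def __init__(self, params: Dict[str, Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * p.grad
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * p.grad**2
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p.value -= self.lr * mh / (np.sqrt(vh) + self.eps)
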