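"""NumPy neural-network layers with explicit forward/backward passes.

Conventions
-----------
* Activations are float32 arrays shaped ``(N, C, H, W)`` (or ``(N, F)`` for
  linear layers).
* ``forward(x, train=...)`` caches whatever ``backward`` needs; ``backward``
  receives the gradient of the loss w.r.t. the layer output and returns the
  gradient w.r.t. the layer input, accumulating parameter gradients in place.
* Layers are deliberately stateless across batches except for parameters and
  BatchNorm running statistics, so a fixed seed gives bit-reproducible runs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr


class Parameter:
    """A learnable tensor with its gradient and momentum buffer."""

    __slots__ = ("value", "grad", "momentum")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.momentum = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_bytes(self) -> bytes:
        """Serialized parameter (and buffer) state, for immutability checks."""
        chunks = [p.value.tobytes() for p in self.parameters()]
        for attr in vars(self).values():
            if isinstance(attr, Module):
                chunks.append(attr.state_bytes())
            elif isinstance(attr, (list, tuple)):
                chunks.extend(m.state_bytes() for m in attr if isinstance(m, Module))
        if isinstance(self, BatchNorm2d):
            chunks.append(self.running_mean.tobytes())
            chunks.append(self.running_var.tobytes())
        return b"".join(chunks)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow)


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, oh: int, ow: int):
    n, c, h, w = x_shape
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


class Conv2d(Module):
    """2-D convolution (cross-correlation) via im2col, with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 1, padding: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel * kernel
        scale = math.sqrt(2.0 / fan_in)  # He initialization
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_channels, fan_in)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))
        self._cache = None

    def forward(self, x, train=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, (oh, ow) = _im2col(x, self.kernel, self.stride, self.padding)
        out = np.matmul(self.weight.value, cols) + self.bias.value[:, None]
        self._cache = (x.shape, cols, oh, ow)
        n = x.shape[0]
        return out.reshape(n, self.out_channels, oh, ow)

    def backward(self, dout):
        x_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        dout = dout.reshape(n, self.out_channels, oh * ow).astype(np.float32)
        self.weight.grad += np.einsum("nol,ncl->oc", dout, cols, optimize=True)
        self.bias.grad += dout.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dout)
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.padding, oh, ow)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        # standard batch-norm backward collapsed over (N, H, W) per channel
        term1 = dxhat
        term2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        term3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (term1 - term2 - term3) * inv_std[None, :, None, None]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_features, in_features)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))
        self._cache = None

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=np.float32)
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout):
        x = self._cache
        dout = dout.astype(np.float32)
        self.weight.grad += dout.T @ x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GELU(Module):
    """Exact Gaussian-error-linear unit, x * Phi(x)."""

    def forward(self, x, train=True):
        self._x = x
        self._cdf = ndtr(x).astype(np.float32)
        return x * self._cdf

    def backward(self, dout):
        x = self._x
        pdf = np.exp(-0.5 * x * x, dtype=np.float32) / np.float32(math.sqrt(2 * math.pi))
        return dout * (self._cdf + x * pdf)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / np.float32(h * w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
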