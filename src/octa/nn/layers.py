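"""Minimal CPU neural-network layers with explicit reverse-mode gradients.

Each layer caches what its backward pass needs during ``forward`` and
returns the input gradient from ``backward`` while accumulating
parameter gradients in-place.  Shapes follow the (batch, channel,
height, width) convention.  Everything is plain float64 NumPy, so runs
are bit-reproducible on a single CPU; correctness of every backward
pass is pinned by central-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "InstanceNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "Upsample2d",
    "Linear",
    "SEBlock",
]


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    __call__ = forward


class Conv2d(Layer):
    """k×k convolution, zero padding `same` (k odd) or none (k=1 trivially same)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        if k % 2 != 1:
            raise ValueError("only odd kernel sizes supported")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.w = Param(rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        y = np.einsum("bchwij,ocij->bohw", win, self.w.value, optimize=True)
        y += self.b.value[None, :, None, None]
        if train:
            self._cache = (win, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win, xshape = self._cache
        self.w.grad += np.einsum("bohw,bchwij->ocij", dy, win, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        b, c, h, w = xshape
        p = self.k // 2
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += np.einsum(
                    "bohw,oc->bchw", dy, self.w.value[:, :, i, j], optimize=True
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._cache: tuple | None = None
        self._calibration: list | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def start_calibration(self) -> None:
        """Begin collecting batch moments to replace the running statistics.

        Exponential running averages track the *last* batches of an
        epoch, which for heavy-tailed activations (speckle intensities)
        can be far from the population moments and make eval-mode
        output depend on shuffle order.  Calibration instead sets the
        statistics to the average of batch moments over a fixed data
        slice ("precise BN").
        """
        self._calibration = []

    def finish_calibration(self) -> None:
        means = np.stack([m for m, _ in self._calibration])
        variances = np.stack([v for _, v in self._calibration])
        self.running_mean = means.mean(axis=0)
        self.running_var = variances.mean(axis=0)
        self._calibration = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._calibration is not None:
                self._calibration.append((mean, var))
            else:
                self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
                self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel spatial normalization with affine parameters.

    Unlike batch normalization it has no batch-size dependence and no
    running statistics, so train- and eval-mode outputs coincide — the
    safer choice for heavy-tailed inputs (speckle intensities) and the
    tiny batch sizes used here.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(2, 3), keepdims=True)
        return (inv_std / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2; deterministic tie-break (first maximum)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h}, {w}) not divisible by 2")
        blocks = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h // 2, w // 2, 4
        )
        self._idx = blocks.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(blocks, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dblocks = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(dblocks, self._idx[..., None], dy[..., None], axis=-1)
        return dblocks.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            b, c, h, w
        )


class Upsample2d(Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.standard_normal((n_out, n_in)) * np.sqrt(2.0 / n_in))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool each channel to a length-C descriptor.
    Excitation: two-layer bottleneck MLP (C → C/r → C) with ReLU inside
    and a logistic-sigmoid gate; each channel is rescaled by its gate,
    which lies strictly in (0, 1) for finite weights.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator | None = None):
        if channels % reduction != 0:
            raise ValueError(f"channels={channels} not divisible by reduction={reduction}")
        self.fc1 = Linear(channels, channels // reduction, rng)
        self.fc2 = Linear(channels // reduction, channels, rng)

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        s = x.mean(axis=(2, 3))
        z1 = self.fc1.forward(s, train)
        a1 = np.maximum(z1, 0.0)
        z2 = self.fc2.forward(a1, train)
        g = 1.0 / (1.0 + np.exp(-z2))
        self._cache = (x, z1, g)
        return x * g[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z1, g = self._cache
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dz2 = dg * g * (1.0 - g)
        da1 = self.fc2.backward(dz2)
        dz1 = da1 * (z1 > 0)
        ds = self.fc1.backward(dz1)
        hw = x.shape[2] * x.shape[3]
        return dx + ds[:, :, None, None] / hw

    def gates(self, x: np.ndarray) -> np.ndarray:
        """The excitation gate vector for an input batch (diagnostics)."""
        s = x.mean(axis=(2, 3))
        a1 = np.maximum(self.fc1.forward(s, train=False), 0.0)
        return 1.0 / (1.0 + np.exp(-self.fc2.forward(a1, train=False)))
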