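"""Minimal NumPy neural-network primitives for 1D sequence models.

Implements exactly the layers the splice model needs -- dilated 1D
convolution with 'same' padding, batch normalization, leaky ReLU -- each
with a hand-written backward pass, plus a decoupled-weight-decay Adam
(AdamW) optimizer.  Tensors are (batch, length, channels) float32.

Each layer instance is used at most once per forward pass, so the forward
cache needed by backward lives on the instance itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Conv1d", "BatchNorm1d", "LeakyReLU", "AdamW"]


class Parameter:
    """A learnable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("name", "data", "grad", "trainable")

    def __init__(self, name: str, data: np.ndarray, trainable: bool = True):
        self.name = name
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.trainable = trainable

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Conv1d:
    """Dilated 1D convolution with 'same' zero padding (odd kernel only).

    Weight layout is (kernel, in_channels, out_channels); the forward pass
    is a sum over kernel taps of shifted (N*L, C_in) @ (C_in, C_out)
    matmuls, which keeps everything inside BLAS.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 1,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("kernel size must be odd and positive")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel
        std = np.sqrt(2.0 / fan_in)  # Kaiming fan-in for leaky-ReLU nets
        self.kernel = kernel
        self.dilation = dilation
        self.weight = Parameter(
            f"{name}.weight",
            rng.normal(0.0, std, size=(kernel, in_channels, out_channels)),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels))
        self._cache: tuple | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, L, _ = x.shape
        p = self.pad
        if p:
            xpad = np.zeros((n, L + 2 * p, x.shape[2]), dtype=np.float32)
            xpad[:, p : p + L, :] = x
        else:
            xpad = x
        w = self.weight.data
        y = np.empty((n, L, w.shape[2]), dtype=np.float32)
        y[:] = self.bias.data
        d = self.dilation
        for k in range(self.kernel):
            y += xpad[:, k * d : k * d + L, :] @ w[k]
        if training:
            self._cache = (xpad, L)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xpad, L = self._cache
        n = dy.shape[0]
        p, d = self.pad, self.dilation
        w = self.weight.data
        dy2 = dy.reshape(-1, dy.shape[2])
        self.bias.grad += dy2.sum(axis=0)
        dxpad = np.zeros_like(xpad)
        for k in range(self.kernel):
            xs = xpad[:, k * d : k * d + L, :]
            self.weight.grad[k] += xs.reshape(-1, xs.shape[2]).T @ dy2
            dxpad[:, k * d : k * d + L, :] += dy @ w[k].T
        self._cache = None
        return dxpad[:, p : p + L, :] if p else dxpad

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        name: str = "bn",
    ):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.update_stats = True  # disabled for frozen layers during transfer
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            if self.update_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mean
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        y = self.gamma.data * xhat + self.beta.data
        if training:
            self._cache = (xhat, inv.astype(np.float32))
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        dx = (self.gamma.data * inv / m) * (
            m * dy - dbeta - xhat * dgamma
        )
        self._cache = None
        return dx.astype(np.float32, copy=False)

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class LeakyReLU:
    def __init__(self, negative_slope: float = 0.1):
        self.slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mask = x >= 0
        y = np.where(mask, x, self.slope * x)
        if training:
            self._mask = mask
        return y.astype(np.float32, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx.astype(np.float32, copy=False)

    def params(self) -> list:
        return []


class AdamW:
    """Adam with decoupled weight decay.

    Defaults mirror the common framework defaults: betas (0.9, 0.999),
    eps 1e-8, weight_decay 0.01.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
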