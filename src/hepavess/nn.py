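"""Minimal NumPy CNN engine: the layers, initializers and optimizer the
ResDense U-net needs, with reverse-mode gradients implemented per layer.

Feature maps are channels-last ``(N, H, W, C)`` float32 (cache-friendly for
im2col), and convolutions are evaluated as one BLAS matmul between the patch
matrix and the kernel matrix. Each layer instance caches what its backward
pass needs, so an instance appears exactly once in a network graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest2d",
    "Adam",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """3x3 (or 1x1) convolution, stride 1, spatial size preserved by padding.

    Weights are stored HWIO: ``(k, k, C_in, C_out)``. Evaluated as a sum of
    k*k shifted channel matmuls; every copy and scatter-add then runs over
    large contiguous memory blocks, which is what makes the NumPy path fast.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 pad: int | None = None) -> None:
        self.kernel = kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        self.c_in = c_in
        self.c_out = c_out
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.weight = Param(w, "conv.weight")
        self.bias = Param(np.zeros(c_out), "conv.bias")
        self._xp = None
        self._shifts = None
        self._in_shape = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _shift(self, xp: np.ndarray, i: int, j: int, h: int, w: int) -> np.ndarray:
        n = xp.shape[0]
        return np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(
            n * h * w, self.c_in
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.kernel, self.pad
        self._in_shape = x.shape
        if k == 1:
            self._xp = x
            y = x.reshape(n * h * w, c) @ self.weight.data[0, 0] + self.bias.data
            return y.reshape(n, h, w, self.c_out)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._shifts = [self._shift(xp, i, j, h, w) for i in range(k) for j in range(k)]
        self._pad_shape = xp.shape
        y = None
        for s, w_ij in zip(self._shifts, self.weight.data.reshape(k * k, c, self.c_out)):
            t = s @ w_ij
            y = t if y is None else y.__iadd__(t)
        y += self.bias.data
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        k, p = self.kernel, self.pad
        dy_mat = np.ascontiguousarray(dy).reshape(n * h * w, self.c_out)
        self.bias.grad += dy_mat.sum(axis=0)
        if k == 1:
            x = self._xp
            self._xp = None
            self.weight.grad[0, 0] += x.reshape(n * h * w, c).T @ dy_mat
            return (dy_mat @ self.weight.data[0, 0].T).reshape(n, h, w, c)
        shifts, self._shifts = self._shifts, None
        dxp = np.zeros(self._pad_shape, dtype=np.float32)
        for (i, j), s in zip(((i, j) for i in range(k) for j in range(k)), shifts):
            self.weight.grad[i, j] += s.T @ dy_mat
            dxp[:, i : i + h, j : j + w, :] += (
                dy_mat @ self.weight.data[i, j].T
            ).reshape(n, h, w, c)
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        if not train:
            return dy * (self.gamma.data * inv)
        dxhat = dy * self.gamma.data
        mean_dxhat = dxhat.mean(axis=(0, 1, 2))
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 1, 2))
        return inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, self._mask = self._mask, None
        return np.where(m, dy, np.float32(0.0))


class Sigmoid:
    def __init__(self) -> None:
        self._y = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60), dtype=np.float64))
        y = np.clip(y, 1e-7, 1.0 - 1e-7).astype(np.float32)
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y, self._y = self._y, None
        return (dy * y * (1.0 - y)).astype(np.float32)


class MaxPool2d:
    """2x2 max pooling (spatial dims must be even)."""

    def __init__(self) -> None:
        self._argmax = None
        self._shape = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        blocks = (x.reshape(n, h // 2, 2, w // 2, 2, c)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(n, h // 2, w // 2, 4, c))
        self._argmax = blocks.argmax(axis=3)
        self._shape = x.shape
        return blocks.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        blocks = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(blocks, self._argmax[:, :, :, None, :], dy[:, :, :, None, :],
                          axis=3)
        dx = (blocks.reshape(n, h // 2, w // 2, 2, 2, c)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(n, h, w, c))
        self._argmax = self._shape = None
        return dx


class UpsampleNearest2d:
    """Nearest-neighbour 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Adam with the usual bias correction; betas (0.9, 0.999), no weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
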