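"""Minimal CNN layer library with explicit forward/backward passes.

Implements exactly the pieces the identification models need — 2-D
convolution (im2col + BLAS matmul), batch normalisation, ReLU, linear layers,
global average pooling and Adam — in float32 NCHW layout. Each layer caches
what its backward pass needs; gradients accumulate into ``Param.grad``.
Parameters carry a ``trainable`` flag so backbones can be frozen.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient buffer."""

    __slots__ = ("data", "grad", "trainable", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.trainable = True
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution with 'same' zero padding and square stride."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, ksize, stride
        self.pad = ksize // 2
        fan_in = c_in * ksize * ksize
        self.weight = Param(he_normal(rng, (c_out, c_in, ksize, ksize), fan_in),
                            f"{name}.weight")
        self.bias = Param(np.zeros(c_out, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        b, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        v = v[:, :, ::s, ::s]                       # (B, C, Ho, Wo, k, k)
        ho, wo = v.shape[2], v.shape[3]
        cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
        return np.ascontiguousarray(cols), (b, c, h, w, ho, wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, (b, c, h, w, ho, wo) = self._im2col(x)
        wmat = self.weight.data.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.bias.data
        self._cache = (cols, (b, c, h, w, ho, wo))
        return out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w, ho, wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(b * ho * wo, self.c_out)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.data.shape)
        self.bias.grad += dmat.sum(axis=0)
        dcols = dmat @ self.weight.data.reshape(self.c_out, -1)
        dv = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dv[..., i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(c, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape, train)
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape, train = self._cache
        b, c, h, w = shape
        m = b * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w),
                               self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(he_normal(rng, (d_out, d_in), d_in), f"{name}.weight")
        self.bias = Param(np.zeros(d_out, dtype=np.float32), f"{name}.bias")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dout.T @ x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam over the trainable parameters (frozen ones are skipped)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32)
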