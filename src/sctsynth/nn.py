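"""Minimal seeded 2-D convolutional network engine on numpy.

Layers follow a functional contract — ``forward(x) -> (y, cache)`` and
``backward(cache, grad_y) -> grad_x`` with parameter gradients accumulated
in place — so a network can be run several times inside one update step
(as cycle-consistent training requires) without cache clashes.  Convolution
is im2col + BLAS matmul; everything runs in float32 and is bit-reproducible
for a fixed seed on a fixed platform.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, cache, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with zero padding, stride >= 1, bias."""

    def __init__(self, in_c: int, out_c: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_c, self.out_c = in_c, out_c
        self.w = Parameter(rng.normal(0.0, init_std, size=(out_c, in_c, k, k)))
        self.b = Parameter(np.zeros(out_c))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, oh, ow, k, k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wmat = self.w.value.reshape(self.out_c, -1)
        y = cols @ wmat.T + self.b.value
        y = y.reshape(n, oh, ow, self.out_c).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(y), (cols, x.shape, xp.shape)

    def backward(self, cache, gy):
        cols, x_shape, xp_shape = cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        _, oc, oh, ow = gy.shape
        gflat = gy.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.w.grad += (gflat.T @ cols).reshape(self.w.value.shape)
        self.b.grad += gflat.sum(axis=0)
        gcols = (gflat @ self.w.value.reshape(oc, -1)).reshape(n, oh, ow, c, k, k)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += gcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return gxp[:, :, p : p + h, p : p + w]
        return gxp


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes (no affine)."""

    eps = 1e-5

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = xc * inv
        return y.astype(np.float32), (y, inv)

    def backward(self, cache, gy):
        y, inv = cache
        m = y.shape[2] * y.shape[3]
        gy_mean = gy.mean(axis=(2, 3), keepdims=True)
        gyy_mean = (gy * y).mean(axis=(2, 3), keepdims=True)
        return ((gy - gy_mean - y * gyy_mean) * inv).astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        y = np.maximum(x, 0)
        return y, (x > 0)

    def backward(self, cache, gy):
        return gy * cache


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        y = np.where(x > 0, x, self.slope * x).astype(np.float32)
        return y, (x > 0)

    def backward(self, cache, gy):
        return np.where(cache, gy, self.slope * gy).astype(np.float32)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y.astype(np.float32), y

    def backward(self, cache, gy):
        return (gy * (1.0 - cache * cache)).astype(np.float32)


class UpsampleNearest(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        y = x.repeat(2, axis=2).repeat(2, axis=3)
        return y, x.shape

    def backward(self, cache, gy):
        n, c, h, w = cache
        return gy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, gy):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            gy = l.backward(c, gy)
        return gy


class Residual(Layer):
    def __init__(self, inner: Sequential):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x):
        y, cache = self.inner.forward(x)
        return (x + y).astype(np.float32), cache

    def backward(self, cache, gy):
        return (gy + self.inner.backward(cache, gy)).astype(np.float32)


def n_parameters(net: Layer) -> int:
    return sum(p.size for p in net.params())


def resnet_generator(
    base: int = 64, n_blocks: int = 9, in_c: int = 1, out_c: int = 1,
    rng: np.random.Generator | None = None,
) -> Sequential:
    """Residual-block encoder-decoder translator (tanh output in [-1, 1])."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [
        Conv2d(in_c, base, 7, 1, 3, rng), InstanceNorm(), ReLU(),
        Conv2d(base, base * 2, 3, 2, 1, rng), InstanceNorm(), ReLU(),
        Conv2d(base * 2, base * 4, 3, 2, 1, rng), InstanceNorm(), ReLU(),
    ]
    for _ in range(n_blocks):
        layers.append(
            Residual(
                Sequential(
                    Conv2d(base * 4, base * 4, 3, 1, 1, rng), InstanceNorm(), ReLU(),
                    Conv2d(base * 4, base * 4, 3, 1, 1, rng), InstanceNorm(),
                )
            )
        )
    layers += [
        UpsampleNearest(), Conv2d(base * 4, base * 2, 3, 1, 1, rng), InstanceNorm(), ReLU(),
        UpsampleNearest(), Conv2d(base * 2, base, 3, 1, 1, rng), InstanceNorm(), ReLU(),
        Conv2d(base, out_c, 7, 1, 3, rng), Tanh(),
    ]
    return Sequential(*layers)


def patch_discriminator(
    base: int = 64, in_c: int = 1, rng: np.random.Generator | None = None
) -> Sequential:
    """PatchGAN-style discriminator: outputs a spatial map of realness scores."""
    rng = rng or np.random.default_rng(0)
    return Sequential(
        Conv2d(in_c, base, 4, 2, 1, rng), LeakyReLU(),
        Conv2d(base, base * 2, 4, 2, 1, rng), InstanceNorm(), LeakyReLU(),
        Conv2d(base * 2, base * 4, 4, 2, 1, rng), InstanceNorm(), LeakyReLU(),
        Conv2d(base * 4, base * 8, 4, 1, 1, rng), InstanceNorm(), LeakyReLU(),
        Conv2d(base * 8, 1, 4, 1, 1, rng),
    )


class Adam:
    """Adam with the momentum schedule used for adversarial training."""

    def __init__(self, params: list[Parameter], beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p in self.params:
            p.m *= b1
            p.m += (1 - b1) * p.grad
            p.v *= b2
            p.v += (1 - b2) * p.grad * p.grad
            p.value -= lr * (p.m / bc1) / (np.sqrt(p.v / bc2) + self.eps)
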