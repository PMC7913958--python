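"""Minimal CPU neural-network layers with explicit backpropagation.

The bifocal classifier is small enough to train on a single CPU, so the
layers below implement exactly what the architecture needs: convolution via
im2col and a BLAS matmul, batch normalization, ReLU, 2x2 max pooling, global
average pooling and a fully connected layer, together with the Adam update
rule and the softmax cross-entropy loss.  All activations and parameters are
``float32`` by default (a ``dtype`` argument exists so gradient-check tests
can run in ``float64``).

Tensors are NCHW.  Layers cache what their backward pass needs on ``self``;
a layer therefore processes one batch at a time (forward then backward),
which is how the trainer drives it.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: forward/backward pair plus parameter enumeration."""

    training: bool = True

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def set_training(self, mode: bool) -> None:
        self.training = mode


class Conv2d(Module):
    """k x k convolution, 'same' padding by default, no bias (BN follows)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng if rng is not None else np.random.default_rng()
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = in_channels * k * k
        # He (fan-in) initialization, appropriate for ReLU stacks.
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(out_channels, in_channels, k, k))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype)) if bias else None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        b, c, h, w = x.shape
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        oh, ow = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b * oh * ow, c * k * k)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (cols, (b, c, h, w), (oh, ow))
        return out.reshape(b, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (b, c, h, w), (oh, ow) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(b * oh * ow, self.out_channels)
        self.weight.grad += (dflat.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dflat.sum(axis=0)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        dcols = (dflat @ wmat).reshape(b, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j]
        if p:
            dx = dx[:, :, p:-p, p:-p]
        return dx


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * ivar[:, None, None]
        self._cache = (xhat, ivar.astype(x.dtype))
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dg = (dout * xhat).sum(axis=(0, 2, 3))
        db = dout.sum(axis=(0, 2, 3))
        self.gamma.grad += dg
        self.beta.grad += db
        g = self.gamma.value[:, None, None]
        if self.training:
            dx = (g * ivar[:, None, None] / n) * (
                n * dout - db[:, None, None] - xhat * dg[:, None, None]
            )
        else:
            dx = g * ivar[:, None, None] * dout
        return dx.astype(dout.dtype)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class MaxPool2d(Module):
    """2x2, stride-2 max pooling; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]
        blocks = x.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (b, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (b, c, h, w) = self._cache
        h2, w2 = h // 2, w // 2
        dblocks = np.zeros((b, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dblocks.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, 2 * h2, 2 * w2)
        )
        return dx


class GlobalAvgPool(Module):
    """Spatial mean -> (B, C) feature vector."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape).astype(dout.dtype) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng()
        w = rng.normal(0.0, math.sqrt(1.0 / in_features), size=(out_features, in_features))
        self.weight = Param(w.astype(dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class Sequential(Module):
    def __init__(self, layers: Sequence[Module]):
        self.layers = list(layers)

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for layer in self.layers:
            layer.set_training(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: Iterable[Param], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    b = logits.shape[0]
    probs = softmax(logits)
    w = np.ones(b, dtype=logits.dtype) if class_weights is None else class_weights[labels].astype(logits.dtype)
    wsum = w.sum()
    logp = np.log(np.clip(probs[np.arange(b), labels], 1e-12, None))
    loss = float(-(w * logp).sum() / wsum)
    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits
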