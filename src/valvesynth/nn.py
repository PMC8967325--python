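"""Minimal seeded neural-network core used by the autoencoders and the
volume-regression CNN.

The networks needed here are small, fixed-topology stacks of 2D/3D
convolutions (kernel 3, stride 1, "same" zero padding), 2x / 2x2x2 average
pooling, nearest-neighbour upsampling and dense layers, trained with Adam on
a mean-squared-error loss.  This module implements exactly that, on NumPy
float32 arrays with a channels-last layout, with hand-written backward
passes.  Dense layers run on BLAS; convolutions run through JIT-compiled
direct kernels (``_conv_kernels``) that exploit the zero-dominated inputs.
Everything is single-threaded and deterministic for a fixed seed.

This is not a general autodiff framework: layers cache what their backward
pass needs during ``forward(train=True)`` and release it afterwards.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "Conv",
    "AvgPool",
    "Upsample",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "train",
    "mse",
]

F32 = np.float32


def _he_std(fan_in: int) -> float:
    return math.sqrt(2.0 / fan_in)


def _glorot_std(fan_in: int, fan_out: int) -> float:
    return math.sqrt(2.0 / (fan_in + fan_out))


class Layer:
    """Base class: a differentiable block with (possibly empty) parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def release(self) -> None:
        """Drop forward caches (called after each optimizer step)."""

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    """Fully connected layer, optionally with a fused ReLU."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=F32) -> None:
        super().__init__()
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        std = _he_std(n_in) if activation == "relu" else _glorot_std(n_in, n_out)
        self.W = rng.standard_normal((n_in, n_out), dtype=F32).astype(dtype, copy=False)
        self.W *= std  # in place: the weight matrix can be gigabytes
        self.b = np.zeros(n_out, dtype=dtype)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros(self.W.shape, dtype=self.W.dtype), np.zeros(self.b.shape, dtype=self.b.dtype)]
        self._x: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def forward(self, x, train=False):
        y = x @ self.W
        y += self.b
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
        if train:
            self._x, self._y = x, y
        return y

    def backward(self, grad):
        x, y = self._x, self._y
        if self.activation == "relu":
            grad = grad * (y > 0)
        self.grads[0] += x.T @ grad
        self.grads[1] += grad.sum(axis=0)
        return grad @ self.W.T

    def release(self):
        self._x = self._y = None


class Conv(Layer):
    """N-dimensional convolution, kernel 3, stride 1, zero "same" padding.

    Channels-last: input ``(B, *spatial, c_in)`` -> ``(B, *spatial, c_out)``.
    Kernels are stored ``(3,)*ndim + (c_in, c_out)`` and evaluated by direct
    JIT-compiled loops (see ``_conv_kernels``) whose inner loop runs over
    the output channels and which skip zero input values — the thresholded
    volumes and ReLU activation maps are mostly zero.
    """

    def __init__(self, ndim: int, c_in: int, c_out: int, rng: np.random.Generator,
                 activation: str = "relu", dtype=F32) -> None:
        super().__init__()
        if ndim not in (2, 3):
            raise ValueError("only 2D and 3D convolutions are supported")
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.ndim = ndim
        self.c_in = c_in
        self.c_out = c_out
        self.activation = activation
        k = 3 ** ndim
        fan_in = c_in * k
        std = _he_std(fan_in) if activation == "relu" else _glorot_std(fan_in, c_out * k)
        shape = (3,) * ndim + (c_in, c_out)
        self.W = rng.standard_normal(shape, dtype=F32).astype(dtype, copy=False)
        self.W *= std
        self.b = np.zeros(c_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros(self.W.shape, dtype=self.W.dtype), np.zeros(self.b.shape, dtype=self.b.dtype)]
        self._xp: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def forward(self, x, train=False):
        from . import _conv_kernels as ck

        if x.shape[-1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[-1]}")
        spatial = x.shape[1:-1]
        if len(spatial) != self.ndim:
            raise ValueError(f"expected {self.ndim} spatial dims, got {len(spatial)}")
        pad = ((0, 0),) + ((1, 1),) * self.ndim + ((0, 0),)
        xp = np.ascontiguousarray(np.pad(x, pad))
        y = np.empty((x.shape[0],) + spatial + (self.c_out,), dtype=x.dtype)
        kern = ck.conv2d_forward if self.ndim == 2 else ck.conv3d_forward
        kern(xp, self.W, self.b, y)
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
        if train:
            self._xp, self._y = xp, y
        return y

    def backward(self, grad):
        from . import _conv_kernels as ck

        xp, y = self._xp, self._y
        if self.activation == "relu":
            grad = grad * (y > 0)
        grad = np.ascontiguousarray(grad)
        wgrad = ck.conv2d_wgrad if self.ndim == 2 else ck.conv3d_wgrad
        wgrad(xp, grad, self.grads[0], self.grads[1])
        # input gradient = convolution of the padded output gradient with
        # the spatially flipped kernel, channels transposed
        flip = (slice(None, None, -1),) * self.ndim
        wf = np.ascontiguousarray(np.swapaxes(self.W[flip], -1, -2))
        pad = ((0, 0),) + ((1, 1),) * self.ndim + ((0, 0),)
        gp = np.ascontiguousarray(np.pad(grad, pad))
        gx = np.empty(grad.shape[:-1] + (self.c_in,), dtype=grad.dtype)
        fwd = ck.conv2d_forward if self.ndim == 2 else ck.conv3d_forward
        fwd(gp, wf, np.zeros(self.c_in, dtype=grad.dtype), gx)
        return gx

    def release(self):
        self._xp = self._y = None


class AvgPool(Layer):
    """Average pooling with a fixed 2 (2D) / 2x2x2 (3D) window."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim

    def forward(self, x, train=False):
        spatial = x.shape[1:-1]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial extents {spatial} not divisible by 2")
        shape = [x.shape[0]]
        axes = []
        for i, s in enumerate(spatial):
            shape += [s // 2, 2]
            axes.append(2 + 2 * i)
        shape.append(x.shape[-1])
        self._in_shape = x.shape
        return x.reshape(shape).mean(axis=tuple(axes))

    def backward(self, grad):
        scale = grad / (2 ** self.ndim)
        expand = scale
        for i in range(self.ndim):
            expand = np.repeat(expand, 2, axis=1 + i)
        return expand.reshape(self._in_shape)


class Upsample(Layer):
    """Nearest-neighbour 2x upsampling per spatial axis."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim

    def forward(self, x, train=False):
        out = x
        for i in range(self.ndim):
            out = np.repeat(out, 2, axis=1 + i)
        return out

    def backward(self, grad):
        spatial = grad.shape[1:-1]
        shape = [grad.shape[0]]
        axes = []
        for i, s in enumerate(spatial):
            shape += [s // 2, 2]
            axes.append(2 + 2 * i)
        shape.append(grad.shape[-1])
        return grad.reshape(shape).sum(axis=tuple(axes))


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x, train=False):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    @property
    def params(self):  # type: ignore[override]
        return [p for layer in self.layers for p in layer.params]

    @params.setter
    def params(self, value):  # base-class __init__ assigns []
        pass

    @property
    def grads(self):  # type: ignore[override]
        return [g for layer in self.layers for g in layer.grads]

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def release(self):
        for layer in self.layers:
            layer.release()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_param{j}"] = p
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                src = state[f"layer{i}_param{j}"]
                if src.shape != p.shape:
                    raise ValueError(f"shape mismatch for layer{i}_param{j}: "
                                     f"{src.shape} vs {p.shape}")
                p[...] = src


class Adam:
    """Adam optimizer (Kingma & Ba) with in-place float32 state."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape, dtype=p.dtype) for p in self.params]
        self.v = [np.zeros(p.shape, dtype=p.dtype) for p in self.params]

    #: elements per update slab; bounds temporaries to ~64 MB for huge layers
    SLAB = 1 << 24

    def step(self, grads: Sequence[np.ndarray]) -> None:
        """Apply one update.  The gradient buffers are consumed as scratch
        space (callers re-zero them before the next accumulation)."""
        self.t += 1
        alpha = self.lr * math.sqrt(1 - self.beta2 ** self.t) / (1 - self.beta1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            pf, gf, mf, vf = (a.reshape(-1) for a in (p, g, m, v))
            for s in range(0, pf.size, self.SLAB):
                sl = slice(s, s + self.SLAB)
                ps, gs, ms, vs = pf[sl], gf[sl], mf[sl], vf[sl]
                ms *= self.beta1
                ms += (1 - self.beta1) * gs
                np.multiply(gs, gs, out=gs)
                gs *= 1 - self.beta2
                vs *= self.beta2
                vs += gs
                np.sqrt(vs, out=gs)
                gs += self.eps
                np.divide(ms, gs, out=gs)
                gs *= alpha
                ps -= gs


def mse(pred: np.ndarray, target: np.ndarray) -> float:
    d = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(d * d))


def train(model: Sequential, x: np.ndarray, y: np.ndarray, *,
          epochs: int, batch_size: int, rng: np.random.Generator,
          lr: float = 1e-3, chunk: int | None = None) -> list[float]:
    """Minimize MSE(model(x), y) with Adam; returns per-epoch mean loss.

    Batches larger than ``chunk`` samples are processed by gradient
    accumulation so that peak activation memory stays bounded for 3D inputs.
    """
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if epochs < 1 or batch_size < 1:
        raise ValueError("epochs and batch_size must be >= 1")
    if chunk is None:
        chunk = 4 if x.ndim >= 5 else 64
    opt = Adam(model.params, lr=lr)
    history: list[float] = []
    per_sample = int(np.prod(y.shape[1:]))
    for _ in range(epochs):
        perm = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            model.zero_grads()
            batch_loss = 0.0
            for cstart in range(0, len(idx), chunk):
                cidx = idx[cstart:cstart + chunk]
                xb, yb = x[cidx], y[cidx]
                pred = model.forward(xb, train=True)
                diff = pred - yb
                batch_loss += float(np.mean(diff.astype(np.float64) ** 2)) * len(cidx)
                # d(mean over batch)/d(pred), with the mean taken over the
                # full optimizer batch, not the accumulation chunk
                gscale = 2.0 / (len(idx) * per_sample)
                model.backward((diff * gscale).astype(pred.dtype, copy=False))
            model.release()
            opt.step(model.grads)
            losses.append(batch_loss / len(idx))
            weights.append(len(idx))
        history.append(float(np.average(losses, weights=weights)))
    model.zero_grads()
    return history
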