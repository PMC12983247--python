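"""Minimal neural-network core: layers with explicit backprop and an AdamW optimizer.

Everything is plain float64 numpy. Layers cache what their backward pass
needs on ``forward`` and release it on ``backward``; a layer is therefore
not re-entrant, which is fine for the sequential training loops used here.
All parameter initialisation is driven by an explicit ``numpy.random.Generator``
so that training is bit-reproducible given a seed.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "ReLU",
    "SmoothReLU",
    "Conv1d",
    "ResidualBlock1d",
    "AdaptiveAvgPool1d",
    "Flatten",
    "Sequential",
    "AdamW",
    "softplus",
    "sigmoid",
]


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + exp(x))."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "frozen")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.frozen = False

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; subclasses implement forward/backward and list parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[str, Param]]:
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = _he_init(rng, n_in, (n_in, n_out))
        self.W = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        if not self.W.frozen:
            self.W.grad += x.T @ gout
            self.b.grad += gout.sum(axis=0)
        return gout @ self.W.value.T

    def params(self):
        return [("W", self.W), ("b", self.b)]


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, gout, 0.0)


class SmoothReLU(Layer):
    """Sharpness-controlled softplus: softplus(beta*x)/beta.

    Approaches ReLU as beta grows (so it optimises like a gated unit) while
    staying infinitely differentiable with curvature bounded by beta/4 —
    which keeps the midpoint-rule path integral used for attribution
    converging quadratically instead of stalling on gradient jumps.
    """

    def __init__(self, beta: float = 8.0):
        self.beta = beta
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return softplus(self.beta * x) / self.beta

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        return gout * sigmoid(self.beta * x)


class Conv1d(Layer):
    """1-D convolution, kernel 3, stride 1, same (zero) padding.

    Input/output layout is ``(batch, channels, length)``; implemented by
    gathering the three shifted views and contracting against the kernel.
    """

    KERNEL = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * self.KERNEL
        self.W = Param(_he_init(rng, fan_in, (c_out, c_in, self.KERNEL)))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, L = x.shape
        xp = np.zeros((b, c, L + 2))
        xp[:, :, 1:-1] = x
        self._xp = xp
        # y[b,o,l] = sum_{c,k} W[o,c,k] * xp[b,c,l+k]
        y = np.zeros((b, self.W.value.shape[0], L))
        for k in range(self.KERNEL):
            y += np.einsum("oc,bcl->bol", self.W.value[:, :, k], xp[:, :, k:k + L],
                           optimize=True)
        return y + self.b.value[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, self._xp = self._xp, None
        b, c, Lp2 = xp.shape
        L = Lp2 - 2
        gxp = np.zeros_like(xp)
        for k in range(self.KERNEL):
            if not self.W.frozen:
                self.W.grad[:, :, k] += np.einsum(
                    "bol,bcl->oc", gout, xp[:, :, k:k + L], optimize=True)
            gxp[:, :, k:k + L] += np.einsum(
                "oc,bol->bcl", self.W.value[:, :, k], gout, optimize=True)
        if not self.b.frozen:
            self.b.grad += gout.sum(axis=(0, 2))
        return gxp[:, :, 1:-1]

    def params(self):
        return [("W", self.W), ("b", self.b)]


class ResidualBlock1d(Layer):
    """Two same-channel convolutions with a skip connection: relu(x + conv(relu(conv(x))))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv1d(channels, channels, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(channels, channels, rng)
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2(self.relu1(self.conv1(x)))
        return self.relu_out.forward(x + h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gout)
        gh = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return g + gh

    def params(self):
        out = []
        for name, layer in (("conv1", self.conv1), ("conv2", self.conv2)):
            out += [(f"{name}.{p}", q) for p, q in layer.params()]
        return out


class AdaptiveAvgPool1d(Layer):
    """Average pooling to a fixed output length, torch bin-edge convention."""

    def __init__(self, out_len: int):
        self.out_len = out_len
        self._edges: list[tuple[int, int]] | None = None
        self._in_len = 0

    def _bins(self, L: int) -> list[tuple[int, int]]:
        m = min(self.out_len, L)
        return [(int(np.floor(i * L / m)), int(np.ceil((i + 1) * L / m)))
                for i in range(m)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, L = x.shape
        edges = self._bins(L)
        self._edges, self._in_len = edges, L
        y = np.empty((b, c, len(edges)))
        for i, (s, e) in enumerate(edges):
            y[:, :, i] = x[:, :, s:e].mean(axis=2)
        if len(edges) < self.out_len:  # input shorter than target: zero-pad
            pad = np.zeros((b, c, self.out_len - len(edges)))
            y = np.concatenate([y, pad], axis=2)
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        edges, self._edges = self._edges, None
        gx = np.zeros(gout.shape[:2] + (self._in_len,))
        for i, (s, e) in enumerate(edges):
            gx[:, :, s:e] += gout[:, :, i:i + 1] / (e - s)
        return gx


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        shape, self._shape = self._shape, None
        return gout.reshape(shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out += [(f"{i}.{n}", p) for n, p in layer.params()]
        return out


def named_params(module: Layer, prefix: str = "") -> list[tuple[str, Param]]:
    return [(prefix + n if prefix else n, p) for n, p in module.params()]


def clone_values(params: Iterable[tuple[str, Param]]) -> dict[str, np.ndarray]:
    """Snapshot parameter values (deep copies) keyed by name."""
    return {n: p.value.copy() for n, p in params}


def load_values(params: Iterable[tuple[str, Param]], state: dict[str, np.ndarray]) -> None:
    for n, p in params:
        p.value[...] = state[n]


class AdamW:
    """AdamW with decoupled weight decay; skips frozen parameters."""

    def __init__(self, params: list[tuple[str, Param]], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = [(n, p) for n, p in params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {n: np.zeros_like(p.value) for n, p in self.params}
        self._v = {n: np.zeros_like(p.value) for n, p in self.params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for n, p in self.params:
            if p.frozen:
                continue
            m = self._m[n]
            v = self._v[n]
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     h: float = 1e-6) -> np.ndarray:
    """Central finite differences; test utility for gradient checking."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += h
        xm = x.copy(); xm[idx] -= h
        g[idx] = (f(xp) - f(xm)) / (2 * h)
        it.iternext()
    return g
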