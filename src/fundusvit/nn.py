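"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the pieces the patch-based transformer detector needs:
dense layers, layer normalization, GELU, sigmoid, inverted dropout,
multi-head self-attention, and the Adam / SGD-with-momentum optimizers.
Every layer caches its forward activations and exposes ``backward`` that
returns the gradient with respect to its input while accumulating parameter
gradients in ``layer.grads``.

Weight initialization is Xavier (Glorot) uniform, drawn from a caller-
supplied ``numpy.random.Generator`` so that model construction is fully
reproducible; there is no global random state anywhere in this module.
Arrays are float64 throughout — at the model sizes used here the cost is
negligible and it keeps gradient checks tight.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "Layer", "Dense", "LayerNorm", "GELU", "Sigmoid", "Dropout",
    "MultiHeadAttention", "Adam", "SGDMomentum", "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameter/gradient dicts plus the forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    """Affine map on the last axis: ``y = x @ W + b``."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params["W"] = xavier_uniform(rng, d_in, d_out, (d_in, d_out))
        self.params["b"] = np.zeros(d_out)
        self.zero_grad()

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        x2 = x.reshape(-1, self.d_in)
        d2 = dout.reshape(-1, self.d_out)
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class LayerNorm(Layer):
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-6) -> None:
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(dim)
        self.params["beta"] = np.zeros(dim)
        self.zero_grad()

    def forward(self, x, *, train=False, rng=None):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dout):
        xhat, inv = self._xhat, self._inv
        d = xhat.shape[-1]
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) if d > 1 else np.zeros_like(dout)


class GELU(Layer):
    """Exact Gaussian-error linear unit, ``x * Phi(x)``."""

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        self._cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, dout):
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dout * (self._cdf + x * pdf)


class Sigmoid(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._y = expit(x)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity when ``train=False`` or rate is 0."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MultiHeadAttention(Layer):
    """Multi-head self-attention over a (batch, tokens, dim) sequence.

    Attention probabilities optionally receive dropout in training mode.
    """

    def __init__(self, dim: int, num_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0) -> None:
        super().__init__()
        if dim % num_heads != 0:
            raise ValueError(f"num_heads={num_heads} must divide dim={dim}")
        self.dim, self.h = dim, num_heads
        self.dh = dim // num_heads
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self.params[name] = xavier_uniform(rng, dim, dim, (dim, dim))
            self.params[name.replace("W", "b")] = np.zeros(dim)
        self.attn_drop = Dropout(dropout)
        self.zero_grad()

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, n, _ = x.shape
        return x.reshape(b, n, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, n, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, n, h * dh)

    def forward(self, x, *, train=False, rng=None):
        p = self.params
        self._x = x
        q = self._split(x @ p["Wq"] + p["bq"])
        k = self._split(x @ p["Wk"] + p["bk"])
        v = self._split(x @ p["Wv"] + p["bv"])
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        attn_d = self.attn_drop.forward(attn, train=train, rng=rng)
        ctx = attn_d @ v
        self._cache = (q, k, v, attn, attn_d, ctx)
        return self._merge(ctx) @ p["Wo"] + p["bo"]

    def backward(self, dout):
        p = self.params
        x = self._x
        q, k, v, attn, attn_d, ctx = self._cache
        b, n, _ = x.shape
        merged = self._merge(ctx)
        self.grads["Wo"] += merged.reshape(-1, self.dim).T @ dout.reshape(-1, self.dim)
        self.grads["bo"] += dout.reshape(-1, self.dim).sum(axis=0)
        dctx = self._split(dout @ p["Wo"].T)
        dattn_d = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ dctx
        dattn = self.attn_drop.backward(dattn_d)
        # softmax jacobian applied row-wise
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        x2 = x.reshape(-1, self.dim)
        for name, grad in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            g = self._merge(grad).reshape(-1, self.dim)
            self.grads[name] += x2.T @ g
            self.grads[name.replace("W", "b")] += g.sum(axis=0)
            dx += (g @ p[name].T).reshape(b, n, self.dim)
        return dx


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 weight_decay: float = 0.0, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = _collect(layers)
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k] + self.wd * p
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1 ** self.t)
                vhat = v[k] / (1 - self.b2 ** self.t)
                p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class SGDMomentum:
    """Classical momentum SGD with optional L2 weight decay."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 momentum: float = 0.9, weight_decay: float = 0.0) -> None:
        self.layers = _collect(layers)
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.vel = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for lay, vel in zip(self.layers, self.vel):
            for k, p in lay.params.items():
                g = lay.grads[k] + self.wd * p
                vel[k] = self.mu * vel[k] - lr * g
                p += vel[k]


def _collect(layers: list[Layer]) -> list[Layer]:
    """Flatten nested layers (attention owns a dropout) keeping only parameterized ones."""
    out = []
    for lay in layers:
        if lay.params:
            out.append(lay)
    return out
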