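"""Minimal dense neural-net layers in numpy with explicit backprop.

Every layer caches what its backward pass needs during ``forward`` and
exposes ``P`` (parameters) and ``G`` (gradients) dicts keyed by local
names; the model prefixes these into a flat global namespace.  All
arithmetic is float64.  Gradients are written (not accumulated) on each
backward call, except embedding tables which scatter-add.

The analytic gradients of every layer are validated against central
finite differences in the test suite.
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

SQRT2 = np.sqrt(2.0)
INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
NEG_INF = -1e9  # additive mask for padded attention keys


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x / SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / SQRT2)) + x * INV_SQRT_2PI * np.exp(-0.5 * x * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    """Base: parameter/gradient dicts plus recursive collection."""

    def __init__(self):
        self.P: dict[str, np.ndarray] = {}
        self.G: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for k, v in self.P.items():
            yield prefix + k, v
        for name, child in self._children.items():
            yield from child.named_parameters(prefix + name + ".")

    def named_gradients(self, prefix: str = ""):
        for k, v in self.G.items():
            yield prefix + k, v
        for name, child in self._children.items():
            yield from child.named_gradients(prefix + name + ".")

    def zero_grad(self):
        for g in self.G.values():
            g[...] = 0.0
        for child in self._children.values():
            child.zero_grad()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        super().__init__()
        self.P["W"] = rng.normal(0.0, init_std, size=(n_in, n_out))
        self.P["b"] = np.zeros(n_out)
        self.G["W"] = np.zeros_like(self.P["W"])
        self.G["b"] = np.zeros_like(self.P["b"])

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.P["W"] + self.P["b"]

    def backward(self, d: np.ndarray) -> np.ndarray:
        n_in = self.P["W"].shape[0]
        x2 = self._x.reshape(-1, n_in)
        d2 = d.reshape(-1, d.shape[-1])
        self.G["W"][...] = x2.T @ d2
        self.G["b"][...] = d2.sum(axis=0)
        return d @ self.P["W"].T


class LayerNorm(Module):
    def __init__(self, n: int, eps: float = 1e-12):
        super().__init__()
        self.eps = eps
        self.P["gamma"] = np.ones(n)
        self.P["beta"] = np.zeros(n)
        self.G["gamma"] = np.zeros(n)
        self.G["beta"] = np.zeros(n)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.P["gamma"] + self.P["beta"]

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.G["gamma"][...] = (d * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.G["beta"][...] = d.reshape(-1, d.shape[-1]).sum(axis=0)
        dxhat = d * self.P["gamma"]
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x: np.ndarray, rng=None, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0 or rng is None:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        return d if self._mask is None else d * self._mask


class GeluDense(Module):
    """Dense layer followed by GELU (position-wise feed-forward half)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.dense = self.add_child("dense", Dense(n_in, n_out, rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = self.dense.forward(x)
        return gelu(self._pre)

    def backward(self, d: np.ndarray) -> np.ndarray:
        return self.dense.backward(d * gelu_grad(self._pre))


class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        if hidden % n_heads:
            raise ValueError("hidden size must be divisible by the head count")
        self.h = hidden
        self.nh = n_heads
        self.dh = hidden // n_heads
        self.q = self.add_child("q", Dense(hidden, hidden, rng))
        self.k = self.add_child("k", Dense(hidden, hidden, rng))
        self.v = self.add_child("v", Dense(hidden, hidden, rng))
        self.o = self.add_child("o", Dense(hidden, hidden, rng))
        self.drop = self.add_child("drop", Dropout(dropout))
        self.attn: np.ndarray | None = None  # [B, nh, L, L], pre-dropout

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, l, _ = x.shape
        return x.reshape(b, l, self.nh, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, nh, l, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, l, self.h)

    def forward(self, x: np.ndarray, key_mask: np.ndarray,
                rng=None, train: bool = False) -> np.ndarray:
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = q @ k.swapaxes(-1, -2) / np.sqrt(self.dh)
        scores = scores + np.where(key_mask[:, None, None, :], 0.0, NEG_INF)
        a = softmax(scores)
        self.attn = a
        a_d = self.drop.forward(a, rng, train)
        ctx = a_d @ v
        self._q, self._k, self._v, self._a_d = q, k, v, a_d
        return self.o.forward(self._merge(ctx))

    def backward(self, d: np.ndarray) -> np.ndarray:
        d_ctx = self._split(self.o.backward(d))
        da_d = d_ctx @ self._v.swapaxes(-1, -2)
        dv = self._a_d.swapaxes(-1, -2) @ d_ctx
        da = self.drop.backward(da_d)
        a = self.attn
        dscores = a * (da - (da * a).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ self._k
        dk = dscores.swapaxes(-1, -2) @ self._q
        dx = self.q.backward(self._merge(dq))
        dx = dx + self.k.backward(self._merge(dk))
        dx = dx + self.v.backward(self._merge(dv))
        return dx


class EncoderLayer(Module):
    """Post-norm transformer block: MHSA -> add&norm -> FFN -> add&norm."""

    def __init__(self, hidden: int, intermediate: int, n_heads: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = self.add_child(
            "attn", MultiHeadSelfAttention(hidden, n_heads, dropout, rng))
        self.drop1 = self.add_child("drop1", Dropout(dropout))
        self.ln1 = self.add_child("ln1", LayerNorm(hidden))
        self.ff1 = self.add_child("ff1", GeluDense(hidden, intermediate, rng))
        self.ff2 = self.add_child("ff2", Dense(intermediate, hidden, rng))
        self.drop2 = self.add_child("drop2", Dropout(dropout))
        self.ln2 = self.add_child("ln2", LayerNorm(hidden))

    def forward(self, x: np.ndarray, key_mask: np.ndarray,
                rng=None, train: bool = False) -> np.ndarray:
        a = self.drop1.forward(self.attn.forward(x, key_mask, rng, train), rng, train)
        h = self.ln1.forward(x + a)
        f = self.drop2.forward(self.ff2.forward(self.ff1.forward(h)), rng, train)
        return self.ln2.forward(h + f)

    def backward(self, d: np.ndarray) -> np.ndarray:
        d2 = self.ln2.backward(d)
        dh = d2 + self.ff1.backward(self.ff2.backward(self.drop2.backward(d2)))
        d1 = self.ln1.backward(dh)
        return d1 + self.attn.backward(self.drop1.backward(d1))


class EmbeddingTable(Module):
    def __init__(self, n_rows: int, hidden: int, rng: np.random.Generator,
                 init_std: float = 0.02):
        super().__init__()
        self.P["weight"] = rng.normal(0.0, init_std, size=(n_rows, hidden))
        self.G["weight"] = np.zeros_like(self.P["weight"])

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.P["weight"][ids]

    def backward(self, d: np.ndarray) -> None:
        np.add.at(self.G["weight"], self._ids, d)
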