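"""Minimal transformer building blocks with explicit reverse-mode gradients.

The masked autoencoder used for micrograph representation learning is small
(a few transformer blocks over 64-pixel tokens), so the package implements
it directly in NumPy: each layer caches its forward activations and exposes
a ``backward`` that accumulates parameter gradients and returns the input
gradient.  Everything runs in float64, which keeps training bit-reproducible
for fixed seeds and makes finite-difference gradient checks tight.

Layers follow the pre-LayerNorm ViT convention: ``x + Attn(LN(x))`` then
``x + MLP(LN(x))`` with GELU activations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Parameter",
    "Linear",
    "LayerNorm",
    "Gelu",
    "MultiHeadSelfAttention",
    "Mlp",
    "TransformerBlock",
    "AdamW",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _init_weight(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # Xavier-uniform, the ViT default for linear projections
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = Parameter(_init_weight(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.value.shape
        self.W.grad += x.reshape(-1, d_in).T @ gy.reshape(-1, d_out)
        self.b.grad += gy.reshape(-1, d_out).sum(axis=0)
        return gy @ self.W.value.T

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LayerNorm:
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (gy * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += gy.reshape(-1, d).sum(axis=0)
        gxhat = gy * self.gamma.value
        m1 = gxhat.mean(axis=-1, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (gxhat - m1 - xhat * m2)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class Gelu:
    def __init__(self) -> None:
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x / _SQRT2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return gy * (cdf + x * pdf)

    def parameters(self) -> list[Parameter]:
        return []


class MultiHeadSelfAttention:
    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, N, D = x.shape
        h, dh = self.n_heads, self.head_dim
        qkv = self.qkv.forward(x).reshape(B, N, 3, h, dh)
        q, k, v = (qkv[:, :, i].transpose(0, 2, 1, 3) for i in range(3))  # (B,h,N,dh)
        scale = dh**-0.5
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        scores -= scores.max(axis=-1, keepdims=True)  # numeric stability
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        out = attn @ v  # (B,h,N,dh)
        self._cache = (q, k, v, attn)
        merged = out.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj.forward(merged)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        B, N, D = gy.shape
        h, dh = self.n_heads, self.head_dim
        q, k, v, attn = self._cache
        scale = dh**-0.5
        g_merged = self.proj.backward(gy)
        g_out = g_merged.reshape(B, N, h, dh).transpose(0, 2, 1, 3)
        g_attn = g_out @ v.transpose(0, 1, 3, 2)
        g_v = attn.transpose(0, 1, 3, 2) @ g_out
        # softmax backward
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_q = (g_scores @ k) * scale
        g_k = (g_scores.transpose(0, 1, 3, 2) @ q) * scale
        g_qkv = np.empty((B, N, 3, h, dh))
        g_qkv[:, :, 0] = g_q.transpose(0, 2, 1, 3)
        g_qkv[:, :, 1] = g_k.transpose(0, 2, 1, 3)
        g_qkv[:, :, 2] = g_v.transpose(0, 2, 1, 3)
        return self.qkv.backward(g_qkv.reshape(B, N, 3 * D))

    def parameters(self) -> list[Parameter]:
        return self.qkv.parameters() + self.proj.parameters()


class Mlp:
    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.act = Gelu()
        self.fc2 = Linear(rng, hidden, dim)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(gy)))

    def parameters(self) -> list[Parameter]:
        return self.fc1.parameters() + self.fc2.parameters()


class TransformerBlock:
    """Pre-LN block: x + Attn(LN1(x)), then + MLP(LN2(.))."""

    def __init__(
        self, rng: np.random.Generator, dim: int, n_heads: int, mlp_ratio: float = 4.0
    ):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, n_heads)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(rng, dim, int(round(dim * mlp_ratio)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn.forward(self.ln1.forward(x))
        return x + self.mlp.forward(self.ln2.forward(x))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy + self.ln2.backward(self.mlp.backward(gy))
        return g + self.ln1.backward(self.attn.backward(g))

    def parameters(self) -> list[Parameter]:
        return (
            self.ln1.parameters()
            + self.attn.parameters()
            + self.ln2.parameters()
            + self.mlp.parameters()
        )


class AdamW:
    """Decoupled-weight-decay Adam; decay applies to matrices only."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1.5e-4,
        betas: tuple[float, float] = (0.9, 0.95),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.value.ndim >= 2:
                update = update + self.weight_decay * p.value
            p.value -= lr * update
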