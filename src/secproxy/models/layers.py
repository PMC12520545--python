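"""Neural-network layers built on the autodiff engine.

Weight initialization is Glorot-uniform from a caller-supplied numpy
Generator so that model construction is fully reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Conv1d",
    "LSTM",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "sinusoidal_positions",
]

DTYPE = np.float32


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class: children and own parameters are discovered by attribute."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.parameters(f"{key}.{i}."))
        return out


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int):
        self.w = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, rng, vocab: int, dim: int):
        self.table = Tensor(
            rng.normal(0, 0.5, size=(vocab, dim)).astype(DTYPE), requires_grad=True
        )

    def __call__(self, idx: np.ndarray) -> Tensor:
        return Tensor.embedding(self.table, idx)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self._eps) ** -0.5 * self.gamma + self.beta


class Conv1d(Module):
    """Same-padded 1-D convolution over (B, T, Cin)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3):
        limit = np.sqrt(6.0 / (kernel * c_in + c_out))
        self.k = Tensor(
            rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(DTYPE),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor.conv1d(x, self.k, self.b)


class LSTM(Module):
    """Single LSTM layer (forget-gate bias initialized to 1)."""

    def __init__(self, rng, d_in: int, hidden: int):
        self.w = Tensor(_glorot(rng, d_in, 4 * hidden), requires_grad=True)
        self.u = Tensor(_glorot(rng, hidden, 4 * hidden), requires_grad=True)
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return Tensor.lstm(x, self.w, self.u, self.b)


class MultiHeadSelfAttention(Module):
    def __init__(self, rng, dim: int, heads: int):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H = self.heads
        hd = D // H
        qkv = self.qkv(x).reshape(B, T, 3, H, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, H, T, hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class TransformerLayer(Module):
    """Pre-norm transformer encoder block with ReLU feed-forward."""

    def __init__(self, rng, dim: int, heads: int, ff_mult: int = 4):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(rng, dim, heads)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(rng, dim, ff_mult * dim)
        self.ff2 = Linear(rng, ff_mult * dim, dim)

    def __call__(self, x: Tensor, dropout: float, rng, training: bool) -> Tensor:
        a = self.attn(self.ln1(x)).dropout(dropout, rng, training)
        x = x + a
        f = self.ff2(self.ff1(self.ln2(x)).relu()).dropout(dropout, rng, training)
        return x + f


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encoding, (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    enc = np.zeros((length, dim), dtype=DTYPE)
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc
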