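"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Supports the operations needed by the peptide-property networks:
broadcasting arithmetic, (batched) matmul, reductions, element-wise
nonlinearities, softmax, embedding lookup, concatenation/slicing, plus a
fused LSTM step sequence and a fused 1-D convolution with hand-written
backward passes for speed. Gradients are accumulated into ``Tensor.grad``
by ``backward()`` over a topologically sorted graph.

Double precision is supported throughout (the gradient-check tests run in
float64); training uses float32.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "warmup_cosine_lr", "l1_loss"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=grad.dtype)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self**-1.0

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), backward)

    # -- reductions and shape ops -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._node(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data, dtype=g.dtype)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._node(self.data[idx], (self,), backward)

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._coerce(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        return Tensor._node(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
        )

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - out_data**2))

        return self._node(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1 - out_data))

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return self._node(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._node(np.abs(self.data), (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._node(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator, training: bool):
        if not training or rate <= 0:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask.astype(self.data.dtype))

    # -- embedding ---------------------------------------------------------

    @staticmethod
    def embedding(table: "Tensor", idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx)

        def backward(g):
            if table.requires_grad:
                full = np.zeros_like(table.data, dtype=g.dtype)
                np.add.at(full, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
                table._accum(full)

        return Tensor._node(table.data[idx], (table,), backward)

    # -- fused LSTM --------------------------------------------------------

    @staticmethod
    def lstm(
        x: "Tensor", w: "Tensor", u: "Tensor", b: "Tensor"
    ) -> "Tensor":
        """One LSTM layer over a (B, T, in) input; returns (B, T, H).

        Gate packing along the last axis of ``w``/``u``/``b`` is
        [input, forget, cell, output]; initial state is zero.
        """
        B, T, _ = x.data.shape
        H = u.data.shape[0]
        dtype = x.data.dtype
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        xw = np.matmul(x.data, w.data) + b.data  # (B, T, 4H)
        cache = []
        outs = np.empty((B, T, H), dtype=dtype)
        for t in range(T):
            z = xw[:, t, :] + h @ u.data
            i = 1 / (1 + np.exp(-z[:, :H]))
            f = 1 / (1 + np.exp(-z[:, H : 2 * H]))
            g_ = np.tanh(z[:, 2 * H : 3 * H])
            o = 1 / (1 + np.exp(-z[:, 3 * H :]))
            c_new = f * c + i * g_
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((h.copy(), c.copy(), i, f, g_, o, c_new, tc))
            h, c = h_new, c_new
            outs[:, t, :] = h

        def backward(grad_out):
            dx_w = np.zeros_like(xw)  # gradient wrt (x @ w + b) pre-activations
            du = np.zeros_like(u.data)
            dh_next = np.zeros((B, H), dtype=grad_out.dtype)
            dc_next = np.zeros((B, H), dtype=grad_out.dtype)
            for t in range(T - 1, -1, -1):
                h_prev, c_prev, i, f, g_, o, c_new, tc = cache[t]
                dh = grad_out[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1 - tc**2) + dc_next
                di = dc * g_
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g_**2),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
                dx_w[:, t, :] = dz
                du += h_prev.T @ dz
                dh_next = dz @ u.data.T
            if x.requires_grad:
                x._accum(np.matmul(dx_w, w.data.T))
            if w.requires_grad:
                w._accum(
                    np.einsum("bti,btj->ij", x.data, dx_w, optimize=True)
                )
            if u.requires_grad:
                u._accum(du)
            if b.requires_grad:
                b._accum(dx_w.sum(axis=(0, 1)))

        return Tensor._node(outs, (x, w, u, b), backward)

    # -- fused 1-D convolution (same padding) ------------------------------

    @staticmethod
    def conv1d(x: "Tensor", kernel: "Tensor", bias: "Tensor") -> "Tensor":
        """(B, T, Cin) * (K, Cin, Cout) -> (B, T, Cout), zero-padded."""
        B, T, Cin = x.data.shape
        K, _, Cout = kernel.data.shape
        pad = K // 2
        xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
        # windows: (B, T, Cin, K) -> (B, T, K, Cin)
        windows = windows.transpose(0, 1, 3, 2)
        out = (
            np.einsum("btkc,kco->bto", windows, kernel.data, optimize=True)
            + bias.data
        )

        def backward(g):
            if kernel.requires_grad:
                kernel._accum(
                    np.einsum("btkc,bto->kco", windows, g, optimize=True)
                )
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1)))
            if x.requires_grad:
                gx = np.zeros_like(xp)
                for k in range(K):
                    gx[:, k : k + T, :] += np.einsum(
                        "bto,kco->btc", g, kernel.data[k : k + 1], optimize=True
                    )
                x._accum(gx[:, pad : pad + T, :])

        return Tensor._node(out, (x, kernel, bias), backward)


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error."""
    return (pred - Tensor(np.asarray(target, dtype=pred.data.dtype))).abs().mean()


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self, lr: Optional[float] = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            p.data = p.data - lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps
            )


def warmup_cosine_lr(
    epoch: int, total_epochs: int, warmup_epochs: int, peak_lr: float
) -> float:
    """Linear warm-up to ``peak_lr`` over ``warmup_epochs`` then cosine
    decay to zero at ``total_epochs`` (epoch is 0-based)."""
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return peak_lr * (epoch + 1) / warmup_epochs
    span = max(total_epochs - warmup_epochs, 1)
    progress = (epoch - warmup_epochs) / span
    return peak_lr * 0.5 * (1 + math.cos(math.pi * progress))
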