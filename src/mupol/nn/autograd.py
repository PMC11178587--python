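"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the denoising U-Net needs: dense and
2-D convolutional layers, group normalisation, SiLU, average pooling,
nearest-neighbour upsampling, concatenation, softmax attention products and
masked L1 reduction.  Tensors hold float32 data; gradients are accumulated
into ``.grad`` by :meth:`Tensor.backward` over a topologically sorted tape.

The engine is deliberately small and deterministic — no operator here is
stochastic, so a fixed seed upstream yields bit-identical training runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "linear", "silu", "group_norm", "avg_pool2",
           "upsample2", "concat", "softmax", "matmul", "add", "mul", "mean_abs"]


class Tensor:
    """A node in the autodiff graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # light sugar used by the model code
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):  # scalar
        bb = np.float32(b)

        def backward_s(g):
            a._accum(g * bb)

        return _node(a.data * bb, (a,), backward_s)

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return _node(out_data, (a, b), backward)


def silu(x: Tensor) -> Tensor:
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out_data = x.data * sig

    def backward(g):
        x._accum(g * (sig * (1.0 + x.data * (1.0 - sig))))

    return _node(out_data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w^T + b with x (..., Cin), w (Cout, Cin)."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        x._accum(g @ w.data)
        gw = g.reshape(-1, g.shape[-1]).T @ x.data.reshape(-1, x.data.shape[-1])
        w._accum(gw)
        if b is not None:
            b._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 1) -> Tensor:
    """3x3 (or kxk) same convolution, NCHW, unit stride, zero padding."""
    k = w.data.shape[-1]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    out_data = np.einsum("bchwij,ocij->bohw", sw, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gw = np.einsum("bchwij,bohw->ocij", sw, g, optimize=True)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1 - pad, k - 1 - pad),
                        (k - 1 - pad, k - 1 - pad)))
        swg = sliding_window_view(gp, (k, k), axis=(2, 3))
        wflip = w.data[:, :, ::-1, ::-1]
        gx = np.einsum("bohwij,ocij->bchw", swg, wflip, optimize=True)
        x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    B, C, H, W = x.data.shape
    G = min(groups, C)
    xg = x.data.reshape(B, G, C // G * H * W)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(B, C, H, W)
    out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        gh = (g * gamma.data[None, :, None, None]).reshape(B, G, -1)
        xh = xhat.reshape(B, G, -1)
        n = gh.shape[2]
        gx = inv * (gh - gh.mean(axis=2, keepdims=True)
                    - xh * (gh * xh).mean(axis=2, keepdims=True))
        x._accum(gx.reshape(B, C, H, W))

    return _node(out_data, (x, gamma, beta), backward)


def avg_pool2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    out_data = x.data.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accum(gx)

    return _node(out_data, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        B, C, H2, W2 = g.shape
        gx = g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))
        x._accum(gx)

    return _node(out_data, (x,), backward)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out_data = np.concatenate([a.data, b.data], axis=axis)
    na = a.data.shape[axis]

    def backward(g):
        ga, gb = np.split(g, [na], axis=axis)
        a._accum(ga)
        b._accum(gb)

    return _node(out_data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    return _node(s, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape

    def backward(g):
        x._accum(g.reshape(old))

    return _node(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        x._accum(g.transpose(inv))

    return _node(x.data.transpose(axes), (x,), backward)


def mean_abs(x: Tensor, target: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Masked L1 loss: mean |x - target| over unmasked elements."""
    diff = x.data - np.asarray(target, dtype=np.float32)
    if mask is None:
        n = diff.size
        sgn = np.sign(diff)
        out_data = np.abs(diff).mean()
    else:
        m = np.broadcast_to(np.asarray(mask, bool), diff.shape)
        n = max(int(m.sum()), 1)
        sgn = np.where(m, np.sign(diff), 0.0)
        out_data = np.abs(diff[m]).sum() / n

    def backward(g):
        x._accum(g * sgn / np.float32(n))

    return _node(np.float32(out_data), (x,), backward)
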