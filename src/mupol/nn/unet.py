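"""Time-conditioned U-Net for noise prediction on 16-channel patches.

Encoder-decoder with four resolution levels and channel multipliers
(1, 2, 4, 8): each level a wide residual block (two 3x3 convolutions, group
normalisation, SiLU) with the sinusoidal time-point embedding injected as a
per-channel bias, self-attention at the two coarsest resolutions, average
pooling down / nearest-neighbour up, and skip connections between the
branches.  Input and output both carry the 16 polarisation-state channels.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["UNet", "sinusoidal_embedding"]


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Standard transformer-style sinusoidal embedding of time indices."""
    t = np.asarray(t, dtype=np.float32).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half, dtype=np.float32) / max(half - 1, 1))
    ang = t * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)


class _Module:
    def params(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, _Module):
                out.extend(v.params())
            elif isinstance(v, list):
                for item in v:
                    if isinstance(item, _Module):
                        out.extend(item.params())
        return out


def _he(rng, shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Conv(_Module):
    def __init__(self, rng, cin, cout, k=3):
        self.w = _he(rng, (cout, cin, k, k), cin * k * k)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b, pad=self.pad)


class Linear(_Module):
    def __init__(self, rng, cin, cout):
        self.w = _he(rng, (cout, cin), cin)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x):
        return ag.linear(x, self.w, self.b)


class GroupNorm(_Module):
    def __init__(self, c, groups=8):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.groups = groups

    def __call__(self, x):
        return ag.group_norm(x, self.gamma, self.beta, self.groups)


class ResBlock(_Module):
    """Wide residual block with time-embedding bias injection."""

    def __init__(self, rng, cin, cout, temb_dim, groups=8):
        self.n1 = GroupNorm(cin, groups)
        self.c1 = Conv(rng, cin, cout)
        self.emb = Linear(rng, temb_dim, cout)
        self.n2 = GroupNorm(cout, groups)
        self.c2 = Conv(rng, cout, cout)
        self.skip = Conv(rng, cin, cout, k=1) if cin != cout else None

    def __call__(self, x, temb):
        h = self.c1(ag.silu(self.n1(x)))
        e = self.emb(ag.silu(temb))          # (B, cout)
        e4 = ag.reshape(e, e.shape + (1, 1))  # (B, cout, 1, 1) broadcast bias
        h = ag.add(h, e4)
        h = self.c2(ag.silu(self.n2(h)))
        s = self.skip(x) if self.skip is not None else x
        return ag.add(h, s)


class Attention(_Module):
    """Single-head self-attention over the spatial positions of a map."""

    def __init__(self, rng, c, groups=8):
        self.norm = GroupNorm(c, groups)
        self.qkv = Linear(rng, c, 3 * c)
        self.proj = Linear(rng, c, c)
        self.c = c

    def __call__(self, x):
        B, C, H, W = x.shape
        h = self.norm(x)
        h = ag.reshape(h, (B, C, H * W))
        h = ag.transpose(h, (0, 2, 1))  # (B, HW, C)
        qkv = self.qkv(h)
        q = _slice_last(qkv, 0, self.c)
        k = _slice_last(qkv, self.c, 2 * self.c)
        v = _slice_last(qkv, 2 * self.c, 3 * self.c)
        att = ag.matmul(q, ag.transpose(k, (0, 2, 1)))
        att = ag.mul(att, 1.0 / np.sqrt(C))
        att = ag.softmax(att, axis=-1)
        out = ag.matmul(att, v)
        out = self.proj(out)
        out = ag.transpose(out, (0, 2, 1))
        out = ag.reshape(out, (B, C, H, W))
        return ag.add(out, x)


def _slice_last(x: Tensor, a: int, b: int) -> Tensor:
    sl = x.data[..., a:b]

    def backward(g):
        full = np.zeros_like(x.data)
        full[..., a:b] = g
        x._accum(full)

    out = Tensor(sl)
    out._parents = (x,)
    out._backward = backward
    return out


class UNet(_Module):
    """epsilon-prediction network consuming (patch, t) pairs.

    Parameters
    ----------
    width:
        Base channel count; levels use width * (1, 2, 4, 8).
    channels:
        Input/output channels (16 polarisation states).
    attn_levels:
        Encoder levels (0-indexed) that receive self-attention; default the
        two coarsest of the four.
    """

    def __init__(self, width: int = 8, channels: int = 16,
                 mults: tuple[int, ...] = (1, 2, 4, 8),
                 attn_levels: tuple[int, ...] = (2, 3),
                 groups: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.channels = channels
        self.mults = tuple(mults)
        self.attn_levels = tuple(attn_levels)
        temb = 4 * width
        self.temb_dim = temb
        self.t1 = Linear(rng, width, temb)
        self.t2 = Linear(rng, temb, temb)
        self.stem = Conv(rng, channels, width)

        chs = [width * m for m in mults]
        self.enc: list[_Module] = []
        self.enc_attn: list[_Module | None] = []
        cin = width
        for i, c in enumerate(chs):
            self.enc.append(ResBlock(rng, cin, c, temb, groups))
            self.enc_attn.append(Attention(rng, c, groups) if i in attn_levels else None)
            cin = c
        self.mid1 = ResBlock(rng, cin, cin, temb, groups)
        self.mid_attn = Attention(rng, cin, groups)
        self.mid2 = ResBlock(rng, cin, cin, temb, groups)
        self.dec: list[_Module] = []
        for i in reversed(range(len(chs))):
            cskip = chs[i]
            cout = chs[i - 1] if i > 0 else width
            self.dec.append(ResBlock(rng, cin + cskip, cout, temb, groups))
            cin = cout
        self.out_norm = GroupNorm(width, groups)
        self.out_conv = Conv(rng, width, channels)

    def params(self) -> list[Tensor]:
        out = super().params()
        for m in self.enc + self.dec:
            out.extend(m.params())
        for m in self.enc_attn:
            if m is not None:
                out.extend(m.params())
        return out

    def __call__(self, x: Tensor, t: np.ndarray) -> Tensor:
        """x: (B, 16, H, W) Tensor in [-1, 1]; t: (B,) integer time indices."""
        temb = Tensor(sinusoidal_embedding(t, self.width))
        temb = self.t2(ag.silu(self.t1(temb)))
        h = self.stem(x)
        skips = []
        n = len(self.enc)
        for i in range(n):
            h = self.enc[i](h, temb)
            if self.enc_attn[i] is not None:
                h = self.enc_attn[i](h)
            skips.append(h)
            if i < n - 1:
                h = ag.avg_pool2(h)
        h = self.mid1(h, temb)
        h = self.mid_attn(h)
        h = self.mid2(h, temb)
        for j, i in enumerate(reversed(range(n))):
            if j > 0:
                h = ag.upsample2(h)
            h = ag.concat(h, skips[i], axis=1)
            h = self.dec[j](h, temb)
        h = ag.silu(self.out_norm(h))
        return self.out_conv(h)

    # ---- (de)serialisation ---------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        ps = self.params()
        if len(ps) != len(d):
            raise ValueError("checkpoint does not match architecture")
        for i, p in enumerate(ps):
            arr = np.asarray(d[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr


class Adam:
    """Adam optimiser over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
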