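"""Neural-network layers built on the autodiff engine (NCDHW layout)."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concat, conv3d, upsample_nearest3d

__all__ = [
    "Module", "Conv3d", "Linear", "GroupNorm", "SelfAttention3d",
    "ResBlock3d", "Downsample3d", "Upsample3d", "VoxelShuffleUpsample3d",
    "timestep_embedding",
]


class Module:
    """Tiny module base: parameter registration via attribute discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            items = (
                [v] if isinstance(v, (Tensor, Module))
                else list(v) if isinstance(v, (list, tuple)) else []
            )
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(s, dtype=np.float32).copy()


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution with He-style fan-in init."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel ** 3
        scale = 0.0 if zero_init else math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, scale or 1e-8, (cout, cin, kernel, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.padding = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        scale = 0.0 if zero_init else math.sqrt(1.0 / nin)
        self.weight = Tensor(rng.normal(0.0, scale or 1e-8, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization over channel groups of an NCDHW tensor."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        while channels % groups != 0:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, d, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * d * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * (var + self.eps) ** -0.5
        return xn.reshape(n, c, d, h, w) * self.gamma + self.beta


class SelfAttention3d(Module):
    """Single-head self-attention over flattened spatial positions."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.norm = GroupNorm(channels)
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)
        self.proj = Linear(channels, channels, rng, zero_init=True)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        n, c, d, h, w = x.shape
        s = d * h * w
        xn = self.norm(x)
        flat = xn.reshape(n, c, s).transpose(0, 2, 1)  # (N, S, C)
        q, k, v = self.q(flat), self.k(flat), self.v(flat)
        attn = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(c))
        attn = attn.softmax(axis=-1)
        out = self.proj(attn @ v)
        out = out.transpose(0, 2, 1).reshape(n, c, d, h, w)
        return x + out


class ResBlock3d(Module):
    """GroupNorm + SiLU + 3x3x3 conv residual block with optional time embedding."""

    def __init__(self, cin: int, cout: int, time_dim: int | None = None,
                 rng: np.random.Generator | None = None):
        self.norm1 = GroupNorm(cin)
        self.conv1 = Conv3d(cin, cout, rng=rng)
        self.norm2 = GroupNorm(cout)
        self.conv2 = Conv3d(cout, cout, rng=rng, zero_init=True)
        self.temb_proj = Linear(time_dim, cout, rng) if time_dim else None
        self.skip = Conv3d(cin, cout, kernel=1, rng=rng) if cin != cout else None

    def __call__(self, x: Tensor, temb: Tensor | None = None) -> Tensor:
        h = self.conv1(self.norm1(x).silu())
        if self.temb_proj is not None and temb is not None:
            b = self.temb_proj(temb)  # (N, Cout)
            h = h + b.reshape(b.shape[0], b.shape[1], 1, 1, 1)
        h = self.conv2(self.norm2(h).silu())
        s = x if self.skip is None else self.skip(x)
        return s + h


class Downsample3d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.conv = Conv3d(cin, cout, stride=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


class Upsample3d(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.conv = Conv3d(cin, cout, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(upsample_nearest3d(x, 2))


class VoxelShuffleUpsample3d(Module):
    """Sub-pixel 2x upsampling: conv to 8x channels at low resolution, then
    rearrange each channel octet into a 2x2x2 spatial block.  Cheaper than
    conv-after-upsample and able to place sub-cell detail."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        self.conv = Conv3d(cin, cout * 8, rng=rng)
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x)
        n, _, d, hh, w = h.shape
        c = self.cout
        h = h.reshape(n, c, 2, 2, 2, d, hh, w)
        h = h.transpose(0, 1, 5, 2, 6, 3, 7, 4)  # (n, c, d, 2, h, 2, w, 2)
        return h.reshape(n, c, 2 * d, 2 * hh, 2 * w)


def timestep_embedding(t: np.ndarray | int, dim: int, max_period: float = 10000.0) -> Tensor:
    """Sinusoidal timestep features of length ``dim`` (must be even)."""
    if dim % 2 != 0:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-math.log(max_period) * np.arange(half) / half)
    args = t[:, None] * freqs[None, :]
    return Tensor(np.concatenate([np.sin(args), np.cos(args)], axis=1))
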