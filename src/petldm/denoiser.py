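"""Conditional 3D diffusion U-Net predicting the corrupting noise.

eps_theta(z_t, t, c(x)): the noisy latent is concatenated channel-wise with
the CT-derived condition, a sinusoidal timestep embedding is injected into
every residual block, and self-attention operates at the two deepest levels
of the three-level channel ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Conv3d, Downsample3d, GroupNorm, Linear, Module, ResBlock3d,
                 SelfAttention3d, Tensor, Upsample3d, concat,
                 timestep_embedding)

__all__ = ["DenoiserConfig", "DiffusionUNet3D"]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture of the latent diffusion U-Net.

    ``channels`` is the per-level feature ladder; attention is enabled at
    the two deepest of the three levels.  ``in_channels`` is the latent
    channel count plus one condition channel.
    """

    in_channels: int = 4            # 3 latent + 1 condition
    out_channels: int = 3
    channels: tuple[int, int, int] = (32, 64, 64)
    resblocks_per_level: int = 1
    attention_levels: tuple[bool, bool, bool] = (False, True, True)
    time_embed_dim: int = 64

    def __post_init__(self):
        if self.time_embed_dim % 2 != 0:
            raise ValueError("time_embed_dim must be even")
        if len(self.channels) != len(self.attention_levels):
            raise ValueError("channels and attention_levels must align")


class DiffusionUNet3D(Module):
    """Three-level U-Net with timestep embedding and deep self-attention."""

    def __init__(self, config: DenoiserConfig = DenoiserConfig(),
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c0, c1, c2 = config.channels
        td = config.time_embed_dim
        self.t_mlp1 = Linear(td, td, rng)
        self.t_mlp2 = Linear(td, td, rng)

        self.conv_in = Conv3d(config.in_channels, c0, rng=rng)
        self.down0 = ResBlock3d(c0, c0, td, rng)
        self.attn0 = SelfAttention3d(c0, rng) if config.attention_levels[0] else None
        self.ds1 = Downsample3d(c0, c1, rng)
        self.down1 = ResBlock3d(c1, c1, td, rng)
        self.attn1 = SelfAttention3d(c1, rng) if config.attention_levels[1] else None
        self.ds2 = Downsample3d(c1, c2, rng)

        self.mid1 = ResBlock3d(c2, c2, td, rng)
        self.mid_attn = SelfAttention3d(c2, rng) if config.attention_levels[2] else None
        self.mid2 = ResBlock3d(c2, c2, td, rng)

        self.us1 = Upsample3d(c2, c1, rng)
        self.up1 = ResBlock3d(2 * c1, c1, td, rng)
        self.up_attn1 = SelfAttention3d(c1, rng) if config.attention_levels[1] else None
        self.us2 = Upsample3d(c1, c0, rng)
        self.up0 = ResBlock3d(2 * c0, c0, td, rng)

        self.norm_out = GroupNorm(c0)
        self.conv_out = Conv3d(c0, config.out_channels, rng=rng, zero_init=True)

    def __call__(self, zt: Tensor, t: np.ndarray | int, cond: Tensor) -> Tensor:
        """Predict the noise added to z_t.

        zt: (N, latent_ch, d, h, w); cond: (N, 1, d, h, w); t: scalar or (N,).
        """
        if zt.shape[0] != cond.shape[0] or zt.shape[2:] != cond.shape[2:]:
            raise ValueError(f"latent/condition shapes differ: {zt.shape} vs {cond.shape}")
        x = concat([zt, cond], axis=1)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}")
        t_arr = np.broadcast_to(np.atleast_1d(t), (zt.shape[0],))
        temb = self.t_mlp2(self.t_mlp1(
            timestep_embedding(t_arr, self.config.time_embed_dim)).silu())

        h0 = self.conv_in(x)
        h0 = self.down0(h0, temb)
        if self.attn0 is not None:
            h0 = self.attn0(h0)
        h1 = self.down1(self.ds1(h0), temb)
        if self.attn1 is not None:
            h1 = self.attn1(h1)
        h2 = self.ds2(h1)
        h2 = self.mid1(h2, temb)
        if self.mid_attn is not None:
            h2 = self.mid_attn(h2)
        h2 = self.mid2(h2, temb)

        u1 = self.up1(concat([self.us1(h2), h1], axis=1), temb)
        if self.up_attn1 is not None:
            u1 = self.up_attn1(u1)
        u0 = self.up0(concat([self.us2(u1), h0], axis=1), temb)
        return self.conv_out(self.norm_out(u0).silu())

    def predict_noise(self, zt: Tensor, t, cond: Tensor) -> Tensor:
        return self(zt, t, cond)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))
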