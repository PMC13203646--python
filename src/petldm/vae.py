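"""Stage I: 3D KL-regularized autoencoder for PET volumes.

The encoder predicts a diagonal Gaussian q(z|y) = N(mu(y), diag(sigma^2(y)))
over a 3-channel latent grid downsampled 4x along every axis (two stride-2
stages); a sample is drawn with the reparameterization trick
z = mu + sigma * eps, and the decoder regresses SUV values directly (no
final activation).  Training minimizes

    L_AE = L_recon + w_KL * L_KL + w_p * L_p + w_adv * L_adv

with L1 reconstruction, the closed-form KL to a unit Gaussian, a fixed
multi-scale gradient/intensity perceptual operator, and an optional
least-squares patch-GAN term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Conv3d, GroupNorm, Module, Tensor,
                 VoxelShuffleUpsample3d, conv3d)

__all__ = [
    "EncoderOutput", "VaeLossWeights", "VAE3D", "PatchDiscriminator",
    "reparameterize", "kl_loss", "recon_loss", "perceptual_loss",
    "adversarial_losses", "total_vae_loss",
]


@dataclass
class EncoderOutput:
    """Latent Gaussian parameters; sigma is derived as exp(logvar / 2) > 0."""

    mu: Tensor
    logvar: Tensor

    @property
    def sigma(self) -> Tensor:
        return (self.logvar * 0.5).exp()


@dataclass(frozen=True)
class VaeLossWeights:
    """Composite loss weights (defaults follow the full-model configuration)."""

    w_kl: float = 1e-6
    w_p: float = 0.001
    w_adv: float = 0.01

    def __post_init__(self):
        if min(self.w_kl, self.w_p, self.w_adv) < 0:
            raise ValueError("loss weights must be non-negative")


class VAE3D(Module):
    """KL autoencoder with a [c0, c1, c2] channel ladder and two stride-2 stages.

    A 96x96x64 input maps to 3-channel latents of shape 24x24x16 (spatial
    reduction 4x per axis).
    """

    def __init__(self, channels=(32, 64, 64), latent_channels: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c0, c1, c2 = channels
        self.channels = tuple(channels)
        self.latent_channels = latent_channels
        # encoder
        self.e_in = Conv3d(1, c0, rng=rng)
        self.e_n0 = GroupNorm(c0)
        self.e_b0 = Conv3d(c0, c0, rng=rng)
        self.e_d1 = Conv3d(c0, c1, stride=2, rng=rng)
        self.e_n1 = GroupNorm(c1)
        self.e_b1 = Conv3d(c1, c1, rng=rng)
        self.e_d2 = Conv3d(c1, c2, stride=2, rng=rng)
        self.e_n2 = GroupNorm(c2)
        self.e_b2 = Conv3d(c2, c2, rng=rng)
        self.e_out = Conv3d(c2, 2 * latent_channels, rng=rng)
        # start with a tight posterior (sigma ~ exp(-3)): the reconstruction
        # path then trains on near-deterministic latents instead of having to
        # become robust to unit-scale latent noise first
        self.e_out.bias.data[latent_channels:] = -6.0
        # decoder
        self.d_in = Conv3d(latent_channels, c2, rng=rng)
        self.d_n0 = GroupNorm(c2)
        self.d_b0 = Conv3d(c2, c2, rng=rng)
        self.d_u1 = VoxelShuffleUpsample3d(c2, c1, rng=rng)
        self.d_n1 = GroupNorm(c1)
        self.d_b1 = Conv3d(c1, c1, rng=rng)
        self.d_u2 = VoxelShuffleUpsample3d(c1, c0, rng=rng)
        self.d_n2 = GroupNorm(c0)
        self.d_b2 = Conv3d(c0, c0, rng=rng)
        self.d_out = Conv3d(c0, 1, rng=rng)  # no final activation: direct SUV regression

    def encode(self, y: Tensor) -> EncoderOutput:
        """Encode a (N, 1, D, H, W) PET batch into latent Gaussian parameters."""
        if y.ndim != 5 or y.shape[1] != 1:
            raise ValueError(f"expected (N,1,D,H,W) input, got {y.shape}")
        if any(s % 4 != 0 for s in y.shape[2:]):
            raise ValueError(f"spatial dims must be divisible by 4, got {y.shape[2:]}")
        h = self.e_in(y)
        h = h + self.e_b0(self.e_n0(h).silu())
        h = self.e_d1(h)
        h = h + self.e_b1(self.e_n1(h).silu())
        h = self.e_d2(h)
        h = h + self.e_b2(self.e_n2(h).silu())
        mom = self.e_out(h)
        mu_t = self._half(mom, 0)
        logvar_t = self._half(mom, 1)
        return EncoderOutput(mu=mu_t, logvar=logvar_t)

    def _half(self, mom: Tensor, which: int) -> Tensor:
        lc = self.latent_channels
        n, c, d, h, w = mom.shape
        r = mom.reshape(n, 2, lc, d, h, w)
        # select half via multiplication with a constant mask, then sum axis 1
        sel = np.zeros((1, 2, 1, 1, 1, 1))
        sel[0, which] = 1.0
        return (r * Tensor(sel)).sum(axis=1)

    def decode(self, z: Tensor) -> Tensor:
        """Decode (N, latent_channels, d, h, w) latents to (N, 1, D, H, W)."""
        if z.ndim != 5 or z.shape[1] != self.latent_channels:
            raise ValueError(f"expected (N,{self.latent_channels},d,h,w) latents, got {z.shape}")
        h = self.d_in(z)
        h = h + self.d_b0(self.d_n0(h).silu())
        h = self.d_u1(h)
        h = h + self.d_b1(self.d_n1(h).silu())
        h = self.d_u2(h)
        h = h + self.d_b2(self.d_n2(h).silu())
        return self.d_out(h)


def reparameterize(out: EncoderOutput, noise: np.ndarray | Tensor) -> Tensor:
    """z = mu + sigma * eps (elementwise)."""
    eps = noise if isinstance(noise, Tensor) else Tensor(noise)
    if eps.shape != out.mu.shape:
        raise ValueError(f"noise shape {eps.shape} != mu shape {out.mu.shape}")
    return out.mu + out.sigma * eps


def kl_loss(out: EncoderOutput) -> Tensor:
    """KL(q(z|y) || N(0, I)) = 1/2 sum(mu^2 + sigma^2 - log sigma^2 - 1).

    Reduction: sum over latent elements, mean over the batch axis.
    """
    mu, logvar = out.mu, out.logvar
    per_elem = (mu * mu + logvar.exp() - logvar - 1.0) * 0.5
    n = per_elem.shape[0]
    return per_elem.sum() * (1.0 / n)


def recon_loss(y: Tensor, y_hat: Tensor) -> Tensor:
    """L1 reconstruction: mean absolute difference over all voxels."""
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return (y - y_hat).abs().mean()


# fixed central-difference kernels along each axis, as (3, 1, 3, 3, 3) conv weight
def _grad_weight() -> Tensor:
    w = np.zeros((3, 1, 3, 3, 3))
    for ax in range(3):
        sl = [1, 1, 1]
        sl[ax] = 0
        w[ax, 0][tuple(sl)] = -0.5
        sl[ax] = 2
        w[ax, 0][tuple(sl)] = 0.5
    return Tensor(w)


def _pool_weight() -> Tensor:
    return Tensor(np.full((1, 1, 2, 2, 2), 1.0 / 8.0))


_GRAD_W = _grad_weight()
_POOL_W = _pool_weight()


def perceptual_loss(y: Tensor, y_hat: Tensor, scales: int = 2) -> Tensor:
    """Multi-scale intensity + 3D-gradient feature L1.

    Features are the raw intensities and central-difference gradient
    components at ``scales`` dyadic scales.  All features are linear in the
    input, so the loss is zero iff the inputs are identical and scales
    linearly with the residual magnitude.
    """
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    d = y - y_hat
    total = None
    for s in range(scales):
        g = conv3d(d, _GRAD_W, None, stride=1, padding=1)
        term = d.abs().mean() + g.abs().mean()
        total = term if total is None else total + term
        if s + 1 < scales:
            if min(d.shape[2:]) < 2:
                break
            d = conv3d(d, _POOL_W, None, stride=2, padding=0)
    return total * (1.0 / scales)


class PatchDiscriminator(Module):
    """3-layer strided 3D conv patch discriminator for the LSGAN term."""

    def __init__(self, channels=(16, 32, 64), rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        c0, c1, c2 = channels
        self.c1_ = Conv3d(1, c0, stride=2, rng=rng)
        self.c2_ = Conv3d(c0, c1, stride=2, rng=rng)
        self.c3_ = Conv3d(c1, c2, stride=2, rng=rng)
        self.out = Conv3d(c2, 1, kernel=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1_(x).silu()
        h = self.c2_(h).silu()
        h = self.c3_(h).silu()
        return self.out(h)


def adversarial_losses(y: Tensor, y_hat: Tensor,
                       discriminator: PatchDiscriminator) -> tuple[Tensor, Tensor]:
    """Least-squares GAN terms: (generator term, discriminator term).

    gen  = mean((D(y_hat) - 1)^2)
    disc = 1/2 [ mean((D(y) - 1)^2) + mean(D(y_hat)^2) ]
    """
    d_fake = discriminator(y_hat)
    gen = ((d_fake - 1.0) ** 2.0).mean()
    # discriminator sees the generator output as a constant (detached)
    d_fake_det = discriminator(Tensor(y_hat.data.copy()))
    d_real = discriminator(y)
    disc = (((d_real - 1.0) ** 2.0).mean() + (d_fake_det ** 2.0).mean()) * 0.5
    return gen, disc


def total_vae_loss(recon: Tensor, kl: Tensor, perceptual: Tensor,
                   adversarial: Tensor | float, weights: VaeLossWeights) -> Tensor:
    """L_AE = L_recon + w_KL L_KL + w_p L_p + w_adv L_adv (exact weighted sum)."""
    total = recon + weights.w_kl * kl + weights.w_p * perceptual
    if weights.w_adv > 0:
        total = total + weights.w_adv * adversarial
    return total
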