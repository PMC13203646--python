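"""DDPM machinery in latent space.

The forward process corrupts a clean latent z_0 over T steps,
q(z_t | z_{t-1}) = N(sqrt(alpha_t) z_{t-1}, (1 - alpha_t) I) with
alpha_t = 1 - beta_t, so that z_t can be sampled in closed form:
z_t = sqrt(abar_t) z_0 + sqrt(1 - abar_t) eps with abar_t = prod alpha_s.

The scaled-linear schedule interpolates sqrt(beta) linearly between
sqrt(beta_start) and sqrt(beta_end).  Two reverse steps are provided: the
posterior-mean-only update (``printed``) and standard ancestral DDPM
sampling that adds posterior-variance noise (``ancestral``).  Timesteps are
1-based externally with the convention abar_0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CT_NORM, PET_SUV, Volume3D
from .nn import Tensor

__all__ = [
    "NoiseSchedule", "make_schedule", "forward_sample", "training_loss",
    "reverse_step_printed", "reverse_step_ancestral", "make_condition",
    "sample_pet", "downsample_to",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """beta/alpha/alpha-bar arrays for T timesteps (index 0 holds t=1)."""

    T: int
    beta: np.ndarray
    alpha: np.ndarray
    alpha_bar: np.ndarray

    def abar(self, t: int) -> float:
        """alpha-bar at 1-based timestep t, with abar(0) = 1."""
        if t == 0:
            return 1.0
        return float(self.alpha_bar[t - 1])

    def check_t(self, t: int) -> None:
        if not 1 <= t <= self.T:
            raise ValueError(f"timestep {t} outside [1, {self.T}]")


def make_schedule(T: int = 1000, beta_start: float = 0.0015,
                  beta_end: float = 0.0195, kind: str = "scaled_linear") -> NoiseSchedule:
    """Build a noise schedule; default is the scaled-linear beta rule."""
    if not (0 < beta_start <= beta_end < 1):
        raise ValueError(f"invalid beta range [{beta_start}, {beta_end}]")
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "scaled_linear":
        root = np.linspace(np.sqrt(beta_start), np.sqrt(beta_end), T)
        beta = root ** 2
    elif kind == "linear":
        beta = np.linspace(beta_start, beta_end, T)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alpha = 1.0 - beta
    alpha_bar = np.cumprod(alpha)
    return NoiseSchedule(T=T, beta=beta, alpha=alpha, alpha_bar=alpha_bar)


def forward_sample(z0: np.ndarray, t: int, eps: np.ndarray,
                   s: NoiseSchedule) -> np.ndarray:
    """z_t = sqrt(abar_t) z_0 + sqrt(1 - abar_t) eps."""
    s.check_t(t)
    if np.shape(eps) != np.shape(z0):
        raise ValueError("eps shape must match z0")
    ab = s.abar(t)
    return np.sqrt(ab) * z0 + np.sqrt(1.0 - ab) * eps


def training_loss(eps_pred: Tensor | np.ndarray, eps: np.ndarray):
    """Simple DDPM objective: mean squared error between noise and prediction."""
    if isinstance(eps_pred, Tensor):
        if eps_pred.shape != np.shape(eps):
            raise ValueError("shape mismatch")
        d = eps_pred - Tensor(eps)
        return (d * d).mean()
    if np.shape(eps_pred) != np.shape(eps):
        raise ValueError("shape mismatch")
    return float(np.mean((np.asarray(eps_pred) - eps) ** 2))


def reverse_step_printed(zt: np.ndarray, t: int, eps_pred: np.ndarray,
                         s: NoiseSchedule) -> np.ndarray:
    """Mean-only reverse update:
    z_{t-1} = (z_t - (1-alpha_t)/sqrt(1-abar_t) * eps_pred) / sqrt(alpha_t).
    """
    s.check_t(t)
    a = float(s.alpha[t - 1])
    ab = s.abar(t)
    return (zt - ((1.0 - a) / np.sqrt(1.0 - ab)) * eps_pred) / np.sqrt(a)


def posterior_variance(s: NoiseSchedule, t: int) -> float:
    """beta-tilde_t = (1 - abar_{t-1}) / (1 - abar_t) * beta_t."""
    s.check_t(t)
    return float((1.0 - s.abar(t - 1)) / (1.0 - s.abar(t)) * s.beta[t - 1])


def reverse_step_ancestral(zt: np.ndarray, t: int, eps_pred: np.ndarray,
                           s: NoiseSchedule, noise: np.ndarray) -> np.ndarray:
    """Ancestral DDPM step: printed mean plus sqrt(beta-tilde_t) noise; no
    noise at t = 1 (the posterior variance vanishes there)."""
    if np.shape(noise) != np.shape(zt):
        raise ValueError("noise shape must match zt")
    mean = reverse_step_printed(zt, t, eps_pred, s)
    if t == 1:
        return mean
    return mean + np.sqrt(posterior_variance(s, t)) * noise


def downsample_to(values: np.ndarray, target_shape) -> np.ndarray:
    """Trilinear resize of a 3D array to an exact target shape."""
    src = np.array(values.shape, dtype=float)
    tgt = np.array(target_shape, dtype=float)
    grids = [((np.arange(int(n)) + 0.5) * s / n) - 0.5
             for n, s in zip(tgt, src)]
    coords = np.meshgrid(*grids, indexing="ij")
    return ndimage.map_coordinates(np.asarray(values, dtype=float),
                                   np.stack(coords), order=1, mode="nearest")


def make_condition(ct_norm: Volume3D, latent_spatial_shape,
                   mode: str = "downsample", vae=None) -> np.ndarray:
    """Build the 1-channel conditioning grid c(x) at latent resolution.

    Default mode trilinearly downsamples the normalized CT; ``encoder`` mode
    instead encodes the CT with the Stage-I encoder mean (first latent
    channel), requiring ``vae``.
    """
    if ct_norm.modality != CT_NORM:
        raise ValueError("condition input must be normalized CT")
    if mode == "downsample":
        c = downsample_to(ct_norm.values, latent_spatial_shape)
    elif mode == "encoder":
        if vae is None:
            raise ValueError("encoder conditioning requires a vae")
        x = Tensor(ct_norm.values[None, None])
        out = vae.encode(x)
        c = out.mu.data[0, 0]
        if c.shape != tuple(latent_spatial_shape):
            raise ValueError("encoder latent shape incompatible with target")
    else:
        raise ValueError(f"unknown condition mode {mode!r}")
    return c[None]  # (1, d, h, w)


def sample_latent(denoiser, cond: np.ndarray, s: NoiseSchedule,
                  rng: np.random.Generator, mode: str = "ancestral",
                  clip_z0: float | None = 4.0) -> np.ndarray:
    """Run the reverse chain from z_T ~ N(0, I) to z_0 for one case.

    ``clip_z0`` bounds the implied clean-latent estimate each step (the
    standard clip-denoised stabilizer for normalized latents); the implied
    estimate is z0_hat = (z_t - sqrt(1-abar_t) eps) / sqrt(abar_t), and the
    step then proceeds with the noise consistent with the clipped estimate.
    Set to None for the raw update exactly as printed.
    """
    latent_shape = (denoiser.config.out_channels,) + tuple(cond.shape[1:])
    zt = rng.standard_normal((1,) + latent_shape)
    cond_t = Tensor(cond[None])
    for t in range(s.T, 0, -1):
        eps_pred = denoiser(Tensor(zt), t, cond_t).data.astype(np.float64)
        if clip_z0 is not None:
            ab = s.abar(t)
            z0_hat = (zt - np.sqrt(1.0 - ab) * eps_pred) / np.sqrt(ab)
            z0_hat = np.clip(z0_hat, -clip_z0, clip_z0)
            eps_pred = (zt - np.sqrt(ab) * z0_hat) / np.sqrt(1.0 - ab)
        if mode == "printed":
            zt = reverse_step_printed(zt, t, eps_pred, s)
        elif mode == "ancestral":
            noise = rng.standard_normal(zt.shape)
            zt = reverse_step_ancestral(zt, t, eps_pred, s, noise)
        else:
            raise ValueError(f"unknown sampler mode {mode!r}")
    return zt[0]


def sample_pet(denoiser, ct_norm: Volume3D, s: NoiseSchedule, vae,
               latent_scale: np.ndarray, mode: str = "ancestral",
               seed: int = 0, condition_mode: str = "downsample") -> Volume3D:
    """Synthesize one PET volume from a preprocessed CT.

    Draws z_T from a seeded generator, runs the reverse chain with the CT
    condition concatenated at every step, rescales by the stored latent
    normalization, decodes, and clips to non-negative SUV.
    """
    rng = np.random.default_rng(seed)
    down = 4  # two stride-2 stages in the autoencoder
    latent_spatial = tuple(n // down for n in ct_norm.shape)
    cond = make_condition(ct_norm, latent_spatial, condition_mode, vae)
    z0 = sample_latent(denoiser, cond, s, rng, mode)
    z0 = z0 * np.asarray(latent_scale).reshape(-1, 1, 1, 1)
    y = vae.decode(Tensor(z0[None])).data[0, 0]
    y = np.clip(y, 0.0, None)
    return Volume3D(y, ct_norm.spacing, ct_norm.orientation, PET_SUV)
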