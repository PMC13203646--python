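# Methods

`petldm` implements conditional three-dimensional latent diffusion for
CT-to-PET synthesis, together with the preprocessing, phantom-simulation,
and evaluation machinery needed to exercise the whole pipeline at desk
scale on a single CPU.

## Problem and model

PET uptake is only partially constrained by anatomy: the same CT can
correspond to many plausible uptake patterns, so the CT→PET mapping is
one-to-many and is modelled as a conditional distribution p(y | x) rather
than a deterministic regression. The model is a two-stage latent diffusion
framework:

**Stage I — KL-regularized autoencoder.** An encoder E maps a PET volume y
(SUV units) to a diagonal Gaussian over a 3-channel latent grid,
q(z | y) = N(μ(y), diag(σ²(y))), with two stride-2 stages giving a 4×
spatial reduction per axis (96×96×64 → 3×24×24×16 in the full profile).
Samples use the reparameterization z = μ + σ ⊙ ε. The decoder D regresses
SUV directly (no final activation). Training minimizes

    L_AE = L_recon + w_KL·L_KL + w_p·L_p + w_adv·L_adv

with L_recon = ‖y − D(E(y))‖₁, the closed-form Gaussian KL
L_KL = ½ Σ(μ² + σ² − log σ² − 1) (sum over latent elements, mean over the
batch — the reduction is a config-visible choice), a fixed multi-scale
intensity+gradient perceptual operator L_p, and an optional least-squares
patch-GAN term L_adv. Default weights: w_KL = 1e-6, w_p = 0.001,
w_adv = 0.01 (the toy profile disables the adversarial term).

**Stage II — conditional DDPM in latent space.** The forward process
corrupts a clean latent z₀ through T steps with a scaled-linear beta
schedule, β_t = (√β₁ + (t−1)/(T−1)(√β_T − √β₁))², and the closed form
z_t = √ᾱ_t z₀ + √(1−ᾱ_t) ε, ᾱ_t = Π α_s, ᾱ₀ = 1. A 3-level diffusion U-Net
ε_θ(z_t, t, c(x)) predicts the injected noise from the noisy latent
concatenated channel-wise with a one-channel CT condition c(x) (trilinear
downsample of the window-normalized CT to the latent grid by default; an
encoder-based condition is available). Training minimizes
‖ε − ε_θ(z_t, t, c(x))‖², with t uniform on {1..T} per batch. Sampling
starts from z_T ~ N(0, I) and applies the reverse update

    z_{t−1} = (1/√α_t)(z_t − ((1−α_t)/√(1−ᾱ_t))·ε_θ)

either as-is (`printed`, the posterior mean only) or with additive
posterior-variance noise √β̃_t (`ancestral`, β̃_t = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t,
no noise at t = 1). Latents are normalized by the per-channel SD of
training-set encoder means (stored in the checkpoint) so diffusion operates
near unit variance.

### Numerical and protocol choices

- **Clip-denoised stabilization.** Each reverse step optionally clips the
  implied clean-latent estimate ẑ₀ = (z_t − √(1−ᾱ_t) ε̂)/√ᾱ_t to ±4 and
  proceeds with the noise consistent with the clipped estimate. Without
  it, the mean-only chain can amplify prediction bias by up to 1/√ᾱ_T.
  The raw update, exactly as written above, is available (`clip_z0=None`)
  and is what the oracle-reversal tests exercise.
- **Toy-profile inference protocol** is the deterministic mean-only chain:
  one synthesis per CT under a fixed protocol, reproducible bit-for-bit
  from the seed. Ancestral sampling remains the package default for the
  full profile; it adds sampling diversity at the cost of hallucinated
  focal uptake at toy scale.
- **Toy beta range.** At T = 50 the full-scale range (0.0015–0.0195)
  leaves ᾱ_T ≈ 0.67 — z_T would retain most of the signal while sampling
  assumes a standard-normal prior. The toy profile uses 0.02–0.35 so that
  ᾱ_T ≈ 2×10⁻⁴, matching the terminal corruption of the T = 1000 profile.
- **Tight posterior initialization.** The encoder's log-variance head is
  biased to −6 at initialization so early training reconstructs from
  near-deterministic latents instead of first learning robustness to
  unit-scale latent noise.
- **Timestep indexing** is 1-based externally with ᾱ₀ = 1, making the
  t = 1 reverse step well-defined and the full oracle chain an exact
  inverse (machine precision) of the forward mean process.

### Profiles

| key | full profile | toy profile |
|---|---|---|
| input grid / spacing | 96×96×64 @ 2×2×3 mm | 32×32×16 @ 6×6×6 mm |
| VAE / U-Net channels | [32, 64, 64] | [8, 16, 16] |
| latent | 3 × 24×24×16 | 3 × 8×8×4 |
| attention levels | [off, on, on] | [off, on, on] |
| T, beta range | 1000, 0.0015–0.0195 | 50, 0.02–0.35 |
| optimizer / LR | Adam, 1e-4, batch 2 | Adam, 5e-3 (VAE) / 3e-3 (diffusion), cosine → 5e-4, batch 4 |
| epochs (AE warmup / diffusion) | 5 / 150 | 60 / 500 |
| sampler | ancestral | printed (mean-only) |

The full profile records the published configuration; the toy profile is
the CPU-tractable surface the tests and the acceptance script run. Toy
problem sizes: 80-phantom cohorts (stage I trains on 64, stage II on 48,
8 held out), chosen so the full two-stage run plus evaluation completes in
roughly ten minutes on one CPU core.

## Neural-network engine

All networks run on a small in-repo reverse-mode automatic-differentiation
engine over numpy (float32): broadcasting arithmetic, matmul, reductions,
softmax, SiLU, GroupNorm (composed), single-head self-attention, strided
3×3×3 convolution implemented as 27 offset-shifted GEMMs, nearest and
sub-pixel (voxel-shuffle) upsampling, and Adam. Gradients of every
operation are verified against central finite differences in the test
suite. The U-Net uses GroupNorm+SiLU residual blocks with a sinusoidal
timestep embedding projected into each block and zero-initialized residual
output convolutions.

## Preprocessing

Volumes are reoriented to RAS (nibabel orientation transforms), resampled
to a common spacing by voxel-centre interpolation (linear for images,
nearest for masks), CT is clipped to an HU window (default [−1000, 1000])
and mapped affinely to [−1, 1], PET is clipped to [0, suv_max] (default
30 SUV; no rescaling, since all metrics are computed in SUV space). The
field of view is restricted anatomically: a lung mask — either supplied
externally or derived by the threshold surrogate (HU < −400 inside the
body mask, two largest 26-connected components) — defines the inferior
lung extent, everything from the lung base to the volume top is kept, and
a centred fixed-size crop/pad produces the uniform network input (odd
remainders pad the far side; pads are −1 for normalized CT, 0 for PET and
masks). The body mask B (evaluation mask) is HU > −500, largest component,
holes filled so lungs stay inside B.

## Synthetic phantoms

The generator emulates the minimum structure the translation task relies
on, with every case bit-reproducible from (spec, case seed):

- **Body**: an ellipsoid of soft-tissue HU (40) in air (−1000), semi-axes
  scaled by uniform(0.75, 1.0) per axis with in-plane centre jitter —
  habitus variability of a size real cohorts show.
- **Lungs**: two low-HU (−750) ellipsoids placed relative to the body
  geometry with per-case size/position jitter, kept strictly interior to
  the body (closed cavities), with a "head" region of body above the apex
  so the lung-base crop is meaningful. Lung uptake is scaled to 0.35× the
  soft-tissue background, reflecting the low FDG uptake of aerated lung.
- **Background uptake**: SUV 1.0 modulated by a smooth bounded random
  field (Gaussian-filtered noise through tanh) with 10% coefficient of
  variation — the order of normal-tissue background variability in FDG
  studies.
- **Lesions**: 0–5 spheres per case, radius 4–12 mm in world coordinates
  (rasterized on the grid, so true volumes are analytically checkable),
  SUV drawn uniformly from [4, 12] independently of anatomy, with a mild
  +30 HU CT correlate. Lesions are placed inside the body without touching
  one another (a 26-connectivity separation margin), so component counts
  are exact. Placement failure after a bounded number of attempts raises.
- **Noise**: additive Gaussian (defaults 20 HU, 0.1 SUV), PET clipped at 0.

What the phantoms do **not** emulate: tracer kinetics, scanner PSF and
reconstruction artifacts, attenuation/scatter physics, respiratory motion,
organ-specific physiologic uptake (brain, myocardium, bladder), and
realistic lesion morphology. Passing end-to-end tests on phantoms
demonstrates that the pipeline is wired correctly and that the model can
extract anatomy-conditioned signal — not clinical-grade synthesis quality.

## Evaluation suite

Global SUV-space metrics are restricted to the body mask B: masked MAE;
masked PSNR = 10·log₁₀(Q²/MSE_B) with Q the clipped SUV range (identical
volumes report a documented 300 dB cap rather than infinity); and 3D SSIM
with a uniform 7×7×7 window, c₁ = (0.01·Q)², c₂ = (0.03·Q)², computed with
scipy's uniform filter under reflective edge handling (edge sample
included) and averaged over B.

Lesion-level evaluation labels 26-connected components. Predicted lesions
are components of {ŷ ≥ 2.5 SUV} with ≥ 3 voxels (all three thresholds are
config keys). Matching is greedy one-to-one by descending overlap voxel
count; any overlap ≥ 1 voxel is admissible; ties break toward the smaller
predicted label. TP + FN = N_ref and TP + FP = N_pred hold exactly.
Cohort precision/recall are subject-averaged; subjects with no predictions
(or no reference lesions) are excluded from the respective mean and the
exclusion counts are reported. The false-positive rate is the mean FP
count per scan. Lesion SUV MSE and NMSE(%) are computed over the union of
reference-lesion voxels; volume agreement uses MAPE(%) (ε = 10⁻⁶ guard)
and Pearson r over matched lesion volumes in mm³.

Cohort summaries report mean ± sample SD (n−1) with Student-t 95%
confidence intervals, mean ± t₀.₉₇₅,ₙ₋₁·sd/√n — the convention that
reproduces published interval bounds from published moments at n = 150,
where the normal-quantile interval does not. Paired method comparisons use
the two-sided Wilcoxon signed-rank test (zero differences dropped; exact
null for ≤ 25 non-zero differences, else normal approximation with
corrections), with no multiple-testing adjustment.

## Known limitations

- At the toy scale, the stage-I autoencoder's masked reconstruction error
  plateaus near 0.26 SUV, dominated by body/lung boundary voxels (the
  boundary shell is a large fraction of a 32×32×16 body). Single-sample
  synthesis consequently tracks that floor and does not outperform the
  train-cohort-mean baseline on masked MAE for most held-out phantoms,
  although it clearly beats an unconditional prior and reproduces the
  anatomy of the conditioning CT. The end-to-end comparison is retained
  in the test suite as the honest statement of this limit.
- Sub-voxel lesions (radius ≲ in-plane spacing) are below the latent
  resolution and are not reliably reconstructed by the toy autoencoder.
- The adversarial term and the encoder-based conditioning path are
  implemented and unit-tested but are off in the toy profile, so their
  effect on synthesis quality is not characterized here.
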