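"""Orchestration: run configuration, two-stage training, synthesis, evaluation.

Two named profiles are provided.  ``full`` mirrors the full-scale
configuration (96x96x64 inputs, channel ladders [32, 64, 64], T = 1000) and
is documentation-grade; ``toy`` is the desk-scale profile used by the test
suite (32x32x16 grids, ladders [8, 16, 16], T = 50).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffusion as diff
from . import vae as vae_mod
from .core import save_volume
from .denoiser import DenoiserConfig, DiffusionUNet3D
from .evalmetrics import (EvalContext, detection_metrics, extract_lesions,
                          lesion_nmse_pct, lesion_suv_mse, lesions_from_mask,
                          mae_masked, match_lesions, psnr_masked, ssim3d_masked)
from .nn import Adam, Tensor
from .phantom import PhantomSpec, generate_cohort, load_manifest_case
from .stats import summarize
from .vae import VAE3D, VaeLossWeights

__all__ = ["RunConfig", "train_stage1", "train_stage2", "synthesize",
           "evaluate_cohort", "mean_pet_baseline", "VaeCheckpoint",
           "LdmCheckpoint", "prepare_cases"]


@dataclass(frozen=True)
class RunConfig:
    """All architecture/training hyperparameters for one run."""

    profile: str = "full"
    input_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    latent_channels: int = 3
    vae_channels: tuple[int, int, int] = (32, 64, 64)
    unet_channels: tuple[int, int, int] = (32, 64, 64)
    attention_levels: tuple[bool, bool, bool] = (False, True, True)
    resblocks_per_level: int = 1
    T: int = 1000
    beta_start: float = 0.0015
    beta_end: float = 0.0195
    schedule_kind: str = "scaled_linear"
    sampler_mode: str = "ancestral"
    condition_mode: str = "downsample"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    learning_rate_diffusion: float | None = None  # defaults to learning_rate
    lr_min: float | None = None   # cosine-anneal floor; None = constant LR
    batch_size: int = 2
    epochs_diffusion: int = 150
    warmup_epochs_vae: int = 5
    w_kl: float = 1e-6
    w_p: float = 0.001
    w_adv: float = 0.01
    hu_window: tuple[float, float] = (-1000.0, 1000.0)
    suv_max: float = 30.0
    lesion_threshold: float = 2.5
    lesion_min_voxels: int = 3
    lesion_connectivity: int = 26
    seed: int = 0

    @staticmethod
    def toy(seed: int = 0, **over) -> "RunConfig":
        """Desk-scale profile used by the tests; CPU-tractable."""
        base = dict(
            profile="toy", input_shape=(32, 32, 16), spacing=(6.0, 6.0, 6.0),
            vae_channels=(8, 16, 16), unet_channels=(8, 16, 16),
            # beta range rescaled so the T=50 chain reaches the same terminal
            # corruption (alpha-bar_T ~ 0) as the T=1000 full profile
            T=50, beta_start=0.02, beta_end=0.35,
            learning_rate=5e-3, learning_rate_diffusion=3e-3,
            lr_min=5e-4, batch_size=4,
            epochs_diffusion=500, warmup_epochs_vae=60,
            sampler_mode="printed", w_adv=0.0, seed=seed,
        )
        base.update(over)
        return RunConfig(**base)

    @staticmethod
    def full(seed: int = 0) -> "RunConfig":
        return RunConfig(seed=seed)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key in ("input_shape", "spacing", "vae_channels", "unet_channels",
                    "attention_levels", "hu_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return RunConfig(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def schedule(self) -> diff.NoiseSchedule:
        return diff.make_schedule(self.T, self.beta_start, self.beta_end,
                                  self.schedule_kind)


@dataclass
class VaeCheckpoint:
    state: list[np.ndarray]
    latent_scale: np.ndarray
    config_hash: str
    loss_log: list[dict]

    def build(self, config: RunConfig) -> VAE3D:
        vae = VAE3D(config.vae_channels, config.latent_channels)
        vae.load_state_dict(self.state)
        return vae

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.state)}
        np.savez(path, latent_scale=self.latent_scale,
                 meta=np.array(json.dumps(
                     {"config_hash": self.config_hash, "loss_log": self.loss_log})),
                 **arrays)

    @staticmethod
    def load(path: str | Path) -> "VaeCheckpoint":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        n = len([k for k in z.files if k.startswith("p")])
        return VaeCheckpoint([z[f"p{i}"] for i in range(n)], z["latent_scale"],
                             meta["config_hash"], meta["loss_log"])


@dataclass
class LdmCheckpoint:
    state: list[np.ndarray]
    config_hash: str
    loss_log: list[dict]

    def build(self, config: RunConfig) -> DiffusionUNet3D:
        net = DiffusionUNet3D(DenoiserConfig(
            in_channels=config.latent_channels + 1,
            out_channels=config.latent_channels,
            channels=config.unet_channels,
            attention_levels=config.attention_levels,
            resblocks_per_level=config.resblocks_per_level))
        net.load_state_dict(self.state)
        return net


def _epoch_lr(config: RunConfig, epoch: int, n_epochs: int,
              base: float | None = None) -> float:
    lr0 = config.learning_rate if base is None else base
    if config.lr_min is None or n_epochs <= 1:
        return lr0
    frac = epoch / (n_epochs - 1)
    return config.lr_min + 0.5 * (lr0 - config.lr_min) * \
        (1.0 + np.cos(np.pi * frac))


def _split_indices(n: int, n_train: int, n_val: int, n_test: int):
    if n_train + n_val + n_test > n:
        raise ValueError("split larger than cohort")
    tr = list(range(n_train))
    va = list(range(n_train, n_train + n_val))
    te = list(range(n_train + n_val, n_train + n_val + n_test))
    if set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te):
        raise ValueError("overlapping splits: patient-level leakage")
    return tr, va, te


def prepare_cases(manifest: pd.DataFrame, config: RunConfig,
                  indices=None) -> list[dict]:
    """Load and preprocess manifest cases to network-ready arrays."""
    from .preprocess import preprocess_case

    rows = manifest.iloc[indices] if indices is not None else manifest
    cases = []
    for _, row in rows.iterrows():
        ct, pet, lesions, lungs = load_manifest_case(row)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prep = preprocess_case(
                ct, pet, lung_mask=lungs,
                extra_masks={"lesion": lesions},
                target_spacing=config.spacing,
                target_shape=config.input_shape,
                hu_window=config.hu_window, suv_max=config.suv_max)
        cases.append({"case_id": row["case_id"], **prep})
    return cases


def _pet_batch(cases: list[dict], idx) -> np.ndarray:
    return np.stack([cases[i]["pet"].values for i in idx])[:, None]


def train_stage1(config: RunConfig, cases: list[dict],
                 val_cases: list[dict] | None = None) -> VaeCheckpoint:
    """Train the KL autoencoder on preprocessed PET volumes.

    Returns a checkpoint carrying weights, the per-channel latent
    normalization (SD of encoder means over the training set), the config
    hash, and a per-epoch loss-term log.
    """
    ss = np.random.SeedSequence([config.seed, 1])
    init_rng, order_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    vae = VAE3D(config.vae_channels, config.latent_channels, rng=init_rng)
    weights = VaeLossWeights(config.w_kl, config.w_p, config.w_adv)
    disc = None
    d_opt = None
    if weights.w_adv > 0:
        disc = vae_mod.PatchDiscriminator(rng=init_rng)
        d_opt = Adam(disc.parameters(), lr=config.learning_rate)
    opt = Adam(vae.parameters(), lr=config.learning_rate)
    n = len(cases)
    bs = min(config.batch_size, n)
    log: list[dict] = []
    for epoch in range(config.warmup_epochs_vae):
        opt.lr = _epoch_lr(config, epoch, config.warmup_epochs_vae)
        order = order_rng.permutation(n)
        terms = {"recon": [], "kl": [], "perceptual": [], "adversarial": []}
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            y = Tensor(_pet_batch(cases, idx))
            out = vae.encode(y)
            eps = noise_rng.standard_normal(out.mu.shape)
            z = vae_mod.reparameterize(out, eps)
            y_hat = vae.decode(z)
            recon = vae_mod.recon_loss(y, y_hat)
            kl = vae_mod.kl_loss(out)
            perc = vae_mod.perceptual_loss(y, y_hat)
            if disc is not None:
                gen, d_term = vae_mod.adversarial_losses(y, y_hat, disc)
                adv_val = float(gen.data)
            else:
                gen, d_term, adv_val = 0.0, None, 0.0
            loss = vae_mod.total_vae_loss(recon, kl, perc, gen, weights)
            vae.zero_grad()
            loss.backward()
            opt.step()
            if d_term is not None:
                disc.zero_grad()
                d_term.backward()
                d_opt.step()
            terms["recon"].append(float(recon.data))
            terms["kl"].append(float(kl.data))
            terms["perceptual"].append(float(perc.data))
            terms["adversarial"].append(adv_val)
        entry = {"epoch": epoch, **{k: float(np.mean(v)) for k, v in terms.items()}}
        if val_cases:
            entry["val_mae"] = _val_recon_mae(vae, val_cases)
        log.append(entry)
    # latent normalization: per-channel SD of encoder means over training set
    mus = []
    for i in range(n):
        out = vae.encode(Tensor(_pet_batch(cases, [i])))
        mus.append(out.mu.data[0])
    mus = np.stack(mus)  # (n, C, d, h, w)
    scale = mus.std(axis=(0, 2, 3, 4))
    scale = np.maximum(scale, 1e-8)
    return VaeCheckpoint(vae.state_dict(), scale, config.config_hash(), log)


def _val_recon_mae(vae: VAE3D, cases: list[dict]) -> float:
    """Masked MAE of the deterministic (encoder-mean) reconstruction."""
    maes = []
    for c in cases:
        out = vae.encode(Tensor(c["pet"].values[None, None]))
        y_hat = vae.decode(out.mu).data[0, 0]
        m = c["body"].values
        maes.append(float(np.abs(c["pet"].values - y_hat)[m].mean()))
    return float(np.mean(maes))


def _latents_and_conditions(config: RunConfig, vae: VAE3D, scale: np.ndarray,
                            cases: list[dict]):
    z0s, conds = [], []
    latent_spatial = tuple(s // 4 for s in config.input_shape)
    for c in cases:
        out = vae.encode(Tensor(c["pet"].values[None, None]))
        z0s.append(out.mu.data[0] / scale.reshape(-1, 1, 1, 1))
        conds.append(diff.make_condition(c["ct_norm"], latent_spatial,
                                         config.condition_mode, vae))
    return np.stack(z0s), np.stack(conds)


def train_stage2(config: RunConfig, vae_ckpt: VaeCheckpoint,
                 cases: list[dict]) -> LdmCheckpoint:
    """Train the conditional latent diffusion U-Net with the frozen Stage-I VAE."""
    if vae_ckpt.config_hash != config.config_hash():
        raise ValueError("stage-1 checkpoint was trained under a different config")
    vae = vae_ckpt.build(config)
    z0s, conds = _latents_and_conditions(config, vae, vae_ckpt.latent_scale, cases)
    s = config.schedule()
    ss = np.random.SeedSequence([config.seed, 2])
    init_rng, order_rng, t_rng, eps_rng = (np.random.default_rng(x) for x in ss.spawn(4))
    net = DiffusionUNet3D(DenoiserConfig(
        in_channels=config.latent_channels + 1,
        out_channels=config.latent_channels,
        channels=config.unet_channels,
        attention_levels=config.attention_levels,
        resblocks_per_level=config.resblocks_per_level), rng=init_rng)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n = z0s.shape[0]
    bs = min(config.batch_size, n)
    log: list[dict] = []
    for epoch in range(config.epochs_diffusion):
        opt.lr = _epoch_lr(config, epoch, config.epochs_diffusion,
                           config.learning_rate_diffusion)
        order = order_rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            idx = order[start:start + bs]
            t = int(t_rng.integers(1, s.T + 1))
            eps = eps_rng.standard_normal(z0s[idx].shape)
            zt = diff.forward_sample(z0s[idx], t, eps, s)
            pred = net(Tensor(zt), t, Tensor(conds[idx]))
            loss = diff.training_loss(pred, eps)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append({"epoch": epoch, "mse": float(np.mean(losses))})
    return LdmCheckpoint(net.state_dict(), config.config_hash(), log)


def synthesize(config: RunConfig, vae_ckpt: VaeCheckpoint,
               ldm_ckpt: LdmCheckpoint, cases: list[dict],
               seed: int = 0, out_dir: str | Path | None = None):
    """Generate one PET volume per case from its preprocessed CT."""
    if ldm_ckpt.config_hash != config.config_hash():
        raise ValueError("checkpoint/config mismatch")
    vae = vae_ckpt.build(config)
    net = ldm_ckpt.build(config)
    s = config.schedule()
    outputs = []
    for i, c in enumerate(cases):
        case_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                        % (2 ** 31))
        pet = diff.sample_pet(net, c["ct_norm"], s, vae, vae_ckpt.latent_scale,
                              mode=config.sampler_mode, seed=case_seed,
                              condition_mode=config.condition_mode)
        outputs.append({"case_id": c["case_id"], "pet": pet, "seed": case_seed})
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            save_volume(pet, out_dir / f"{c['case_id']}_synth.nii.gz")
    return outputs


def mean_pet_baseline(train_cases: list[dict]) -> np.ndarray:
    """Voxelwise mean training PET: the naive cohort-average baseline."""
    return np.mean([c["pet"].values for c in train_cases], axis=0)


def evaluate_cohort(pred: list[dict] | dict, cases: list[dict],
                    config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Per-subject metric table plus a cohort summary.

    ``pred`` maps case ids to predicted PET volumes (or is the output list
    of :func:`synthesize`).  Reference PET, body masks, and lesion masks
    come from the preprocessed ``cases``.
    """
    if isinstance(pred, list):
        pred = {p["case_id"]: p["pet"] for p in pred}
    missing = [c["case_id"] for c in cases if c["case_id"] not in pred]
    if missing:
        raise ValueError(f"unmatched case ids: {missing}")
    rows = []
    matches = []
    all_gt_vols, all_pred_vols = [], []
    for c in cases:
        cid = c["case_id"]
        y, y_hat = c["pet"], pred[cid]
        ctx = EvalContext(B=c["body"], Q=config.suv_max)
        gt_set = lesions_from_mask(c["lesion"], config.lesion_connectivity)
        pred_set = extract_lesions(y_hat, config.lesion_threshold,
                                   config.lesion_min_voxels,
                                   config.lesion_connectivity)
        m = match_lesions(gt_set, pred_set)
        matches.append(m)
        row = {
            "case_id": cid,
            "MAE": mae_masked(y, y_hat, ctx),
            "PSNR": psnr_masked(y, y_hat, ctx),
            "SSIM": ssim3d_masked(y, y_hat, ctx),
            "TP": m.tp, "FP": m.fp, "FN": m.fn,
            "precision": m.tp / (m.tp + m.fp) if (m.tp + m.fp) else np.nan,
            "recall": m.tp / (m.tp + m.fn) if (m.tp + m.fn) else np.nan,
            "lesion_mse": lesion_suv_mse(y, y_hat, gt_set) if gt_set.n else np.nan,
            "lesion_nmse_pct": lesion_nmse_pct(y, y_hat, gt_set) if gt_set.n else np.nan,
        }
        rows.append(row)
        for g, p in m.pairs:
            all_gt_vols.append(gt_set.volume_of(g))
            all_pred_vols.append(pred_set.volume_of(p))
    table = pd.DataFrame(rows)
    det = detection_metrics(matches)
    summary = {
        "n": len(cases),
        "config_hash": config.config_hash(),
        "detection": {k: det[k] for k in
                      ("precision", "recall", "lesions_detected", "fp_rate",
                       "n_excluded_precision", "n_excluded_recall")},
    }
    for metric in ("MAE", "PSNR", "SSIM"):
        vals = table[metric].to_numpy(dtype=float)
        if len(vals) >= 2:
            cs = summarize(vals)
            summary[metric] = {"mean": cs.mean, "sd": cs.sd,
                               "ci": [cs.ci_low, cs.ci_high]}
        else:
            summary[metric] = {"mean": float(vals.mean())}
    gt_v = np.asarray(all_gt_vols)
    pr_v = np.asarray(all_pred_vols)
    if gt_v.size >= 1:
        summary["volume_mape_pct"] = float(
            100.0 * np.mean(np.abs(gt_v - pr_v) / (gt_v + 1e-6)))
    if gt_v.size >= 2 and gt_v.std() > 0 and pr_v.std() > 0:
        summary["volume_pearson_r"] = float(np.corrcoef(gt_v, pr_v)[0, 1])
    return table, summary
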