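"""SUV-space and lesion-level evaluation of synthetic PET.

Global metrics (MAE, PSNR, 3D SSIM) are computed inside a body evaluation
mask B; lesion-level metrics cover detection (precision/recall/FP per
scan via connected-component matching), uptake fidelity within reference
lesions (SUV MSE, NMSE %), and lesion volume agreement (MAPE %, Pearson r
over matched pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .core import Mask3D, Volume3D

__all__ = [
    "EvalContext", "Lesion", "LesionSet", "LesionMatch",
    "mae_masked", "psnr_masked", "ssim3d_masked",
    "extract_lesions", "lesions_from_mask", "match_lesions",
    "detection_metrics", "lesion_suv_mse", "lesion_nmse_pct",
    "volume_mape", "volume_pearson", "PSNR_CAP_DB",
]

#: Reported in place of infinite PSNR (identical volumes), keeping cohort
#: means finite; documented sentinel.
PSNR_CAP_DB = 300.0

_CONN = {6: ndimage.generate_binary_structure(3, 1),
         18: ndimage.generate_binary_structure(3, 2),
         26: np.ones((3, 3, 3), dtype=bool)}


@dataclass(frozen=True)
class EvalContext:
    """Evaluation mask and SSIM/PSNR constants.

    Q is the SUV dynamic range after clipping (suv_max - 0); k1/k2 are the
    usual SSIM stabilizer coefficients; the SSIM window is a uniform cube.
    """

    B: Mask3D
    Q: float = 30.0
    k1: float = 0.01
    k2: float = 0.03
    ssim_window: int = 7

    def __post_init__(self):
        if self.Q <= 0:
            raise ValueError("Q must be positive")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise ValueError("SSIM window must be odd and >= 3")


def _masked(y: Volume3D, y_hat: Volume3D, ctx: EvalContext):
    if y.shape != y_hat.shape or y.shape != ctx.B.shape:
        raise ValueError("volumes and mask must share a grid")
    m = ctx.B.values
    if not m.any():
        raise ValueError("empty evaluation mask")
    return y.values[m].astype(np.float64), y_hat.values[m].astype(np.float64)


def mae_masked(y: Volume3D, y_hat: Volume3D, ctx: EvalContext) -> float:
    """Mean absolute SUV deviation over the evaluation mask."""
    a, b = _masked(y, y_hat, ctx)
    return float(np.mean(np.abs(a - b)))


def psnr_masked(y: Volume3D, y_hat: Volume3D, ctx: EvalContext) -> float:
    """10 log10(Q^2 / masked MSE), capped at PSNR_CAP_DB for zero error."""
    a, b = _masked(y, y_hat, ctx)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(ctx.Q ** 2 / mse), PSNR_CAP_DB))


def ssim3d_masked(y: Volume3D, y_hat: Volume3D, ctx: EvalContext) -> float:
    """Mean 3D SSIM over B with a uniform cubic window and reflect padding.

    Per-voxel SSIM uses local means, variances and covariance over the
    window, with stabilizers c1 = (k1 Q)^2, c2 = (k2 Q)^2.
    """
    if y.shape != y_hat.shape or y.shape != ctx.B.shape:
        raise ValueError("volumes and mask must share a grid")
    w = ctx.ssim_window
    if any(n < w for n in y.shape):
        raise ValueError(f"volume smaller than SSIM window {w}")
    a = y.values.astype(np.float64)
    b = y_hat.values.astype(np.float64)

    def lm(x):
        return ndimage.uniform_filter(x, size=w, mode="reflect")

    mu_a, mu_b = lm(a), lm(b)
    var_a = lm(a * a) - mu_a ** 2
    var_b = lm(b * b) - mu_b ** 2
    cov = lm(a * b) - mu_a * mu_b
    c1 = (ctx.k1 * ctx.Q) ** 2
    c2 = (ctx.k2 * ctx.Q) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / \
               ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    m = ctx.B.values
    if not m.any():
        raise ValueError("empty evaluation mask")
    return float(ssim_map[m].mean())


# --------------------------------------------------------------------------
# lesion-level machinery
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Lesion:
    """One connected component: label id, voxel count, volume in mm^3."""

    label: int
    n_voxels: int
    volume_mm3: float


@dataclass
class LesionSet:
    """Labelled connected components of a binary lesion mask."""

    labels: np.ndarray              # 0 = background, 1..n component ids
    lesions: list[Lesion]
    spacing: tuple[float, float, float]

    @property
    def n(self) -> int:
        return len(self.lesions)

    def volume_of(self, label: int) -> float:
        return self.lesions[label - 1].volume_mm3


def lesions_from_mask(mask: Mask3D, connectivity: int = 26,
                      min_voxels: int = 1) -> LesionSet:
    """Label the components of a binary mask as a LesionSet."""
    struct = _CONN[connectivity]
    labels, n = ndimage.label(mask.values, structure=struct)
    vox = float(np.prod(mask.spacing))
    lesions = []
    keep_labels = np.zeros_like(labels)
    nxt = 0
    for lab in range(1, n + 1):
        cnt = int((labels == lab).sum())
        if cnt >= min_voxels:
            nxt += 1
            keep_labels[labels == lab] = nxt
            lesions.append(Lesion(nxt, cnt, cnt * vox))
    return LesionSet(keep_labels, lesions, mask.spacing)


def extract_lesions(pet: Volume3D, threshold: float = 2.5,
                    min_voxels: int = 3, connectivity: int = 26) -> LesionSet:
    """Predicted lesions: components of {SUV >= threshold} with enough voxels."""
    mask = Mask3D(pet.values >= threshold, pet.spacing, pet.orientation)
    return lesions_from_mask(mask, connectivity, min_voxels)


@dataclass
class LesionMatch:
    """One-to-one TP matching between reference and predicted lesion sets."""

    pairs: list[tuple[int, int]]    # (gt label, pred label)
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        assert self.tp == len(self.pairs)


def match_lesions(gt: LesionSet, pred: LesionSet) -> LesionMatch:
    """Greedy one-to-one matching by descending overlap voxel count.

    A pair is admissible iff it overlaps in at least one voxel; ties are
    broken by smaller predicted label, then smaller reference label.
    """
    if gt.labels.shape != pred.labels.shape:
        raise ValueError("lesion sets live on different grids")
    overlaps = []
    for g in gt.lesions:
        gmask = gt.labels == g.label
        plabs = pred.labels[gmask]
        plabs = plabs[plabs > 0]
        if plabs.size:
            uniq, cnt = np.unique(plabs, return_counts=True)
            for p, c in zip(uniq, cnt):
                overlaps.append((int(c), int(p), int(g.label)))
    # sort: overlap desc, pred label asc, gt label asc
    overlaps.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for c, p, g in overlaps:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        pairs.append((g, p))
    tp = len(pairs)
    return LesionMatch(pairs=pairs, tp=tp, fp=pred.n - tp, fn=gt.n - tp)


def detection_metrics(matches: list[LesionMatch]) -> dict:
    """Subject-averaged precision, recall, lesions detected, FP per scan.

    Subjects with no predictions (TP+FP = 0) are excluded from the precision
    mean; subjects with no reference lesions are excluded from the recall
    mean.  Exclusion counts are reported.
    """
    if not matches:
        raise ValueError("need at least one subject")
    precisions, recalls = [], []
    skipped_p = skipped_r = 0
    for m in matches:
        if m.tp + m.fp > 0:
            precisions.append(m.tp / (m.tp + m.fp))
        else:
            skipped_p += 1
        if m.tp + m.fn > 0:
            recalls.append(m.tp / (m.tp + m.fn))
        else:
            skipped_r += 1
    return {
        "precision": float(np.mean(precisions)) if precisions else float("nan"),
        "recall": float(np.mean(recalls)) if recalls else float("nan"),
        "lesions_detected": float(np.mean([m.tp + m.fp for m in matches])),
        "fp_rate": float(np.mean([m.fp for m in matches])),
        "per_subject_precision": precisions,
        "per_subject_recall": recalls,
        "n_excluded_precision": skipped_p,
        "n_excluded_recall": skipped_r,
    }


def _lesion_union(gt: LesionSet) -> np.ndarray:
    return gt.labels > 0


def lesion_suv_mse(y: Volume3D, y_hat: Volume3D, gt: LesionSet) -> float:
    """Mean squared SUV error over the union of reference lesion voxels."""
    L = _lesion_union(gt)
    if not L.any():
        raise ValueError("no reference lesion voxels")
    d = y.values[L].astype(np.float64) - y_hat.values[L].astype(np.float64)
    return float(np.mean(d ** 2))


def lesion_nmse_pct(y: Volume3D, y_hat: Volume3D, gt: LesionSet) -> float:
    """100 * sum((y - y_hat)^2) / sum(y^2) over reference lesion voxels."""
    L = _lesion_union(gt)
    if not L.any():
        raise ValueError("no reference lesion voxels")
    a = y.values[L].astype(np.float64)
    b = y_hat.values[L].astype(np.float64)
    denom = float(np.sum(a ** 2))
    if denom == 0.0:
        raise ValueError("zero uptake in reference lesions")
    return float(100.0 * np.sum((a - b) ** 2) / denom)


def volume_mape(match: LesionMatch, gt: LesionSet, pred: LesionSet,
                eps: float = 1e-6) -> float:
    """Mean absolute percentage error of matched lesion volumes (mm^3)."""
    if match.tp < 1:
        raise ValueError("no matched lesions")
    terms = [abs(gt.volume_of(g) - pred.volume_of(p)) / (gt.volume_of(g) + eps)
             for g, p in match.pairs]
    return float(100.0 * np.mean(terms))


def volume_pearson(match: LesionMatch, gt: LesionSet, pred: LesionSet) -> float:
    """Pearson r between matched reference and predicted lesion volumes."""
    if match.tp < 2:
        raise ValueError("need >= 2 matched lesions for a correlation")
    v = np.array([gt.volume_of(g) for g, _ in match.pairs])
    vh = np.array([pred.volume_of(p) for _, p in match.pairs])
    if v.std() == 0 or vh.std() == 0:
        raise ValueError("degenerate volume variance")
    r, _ = stats.pearsonr(v, vh)
    return float(r)
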