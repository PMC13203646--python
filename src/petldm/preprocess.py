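"""Anatomy-guided preprocessing for paired CT/PET volumes.

Standardizes orientation (RAS), voxel spacing, and intensity ranges, then
restricts the field of view from the lung base superiorly to the head using
a lung mask, and finally crops/pads to a fixed network input size.

The lung mask comes either from an external file or from
:func:`surrogate_lung_mask`, a threshold-based segmenter (HU < −400 inside
the body, two largest components).  Only the inferior lung extent is needed
for the crop, so this surrogate suffices for phantom-scale work.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import CT_HU, CT_NORM, PET_SUV, CropBounds, Mask3D, Volume3D

__all__ = [
    "reorient_to_ras", "resample", "clip_normalize_ct", "clip_pet_suv",
    "surrogate_lung_mask", "lung_base_crop_bounds", "fixed_size_crop_pad",
    "body_mask", "apply_bounds", "preprocess_case",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def reorient_to_ras(v: Volume3D | Mask3D):
    """Permute/flip axes so the volume is in RAS orientation.

    Idempotent; round-tripping through the inverse transform restores the
    input.  Raises on orientation codes nibabel does not recognise.
    """
    code = v.orientation
    try:
        ornt = nib.orientations.axcodes2ornt(tuple(code))
    except Exception as exc:
        raise ValueError(f"unknown orientation code {code!r}") from exc
    if np.isnan(ornt).any():
        raise ValueError(f"unknown orientation code {code!r}")
    target = nib.orientations.axcodes2ornt(("R", "A", "S"))
    xform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(v.values, xform)
    # xform row i sends input axis i to output axis xform[i, 0]; output
    # axis j therefore inherits the spacing of input axis argsort(...)[j]
    perm = np.argsort(xform[:, 0].astype(int))
    spacing = tuple(np.asarray(v.spacing)[perm])
    out = replace(v, values=data, spacing=spacing, orientation="RAS")
    return out


def resample(v: Volume3D | Mask3D, target_spacing, mode: str = "linear"):
    """Resample to a new voxel spacing, preserving physical extent.

    Voxel centres sit at ``(i + 1/2) * spacing``; values are interpolated at
    the new centres (``linear``) or copied from the nearest source voxel
    (``nearest``, which keeps masks binary).
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    src = np.asarray(v.spacing, dtype=float)
    tgt = np.asarray(target_spacing, dtype=float)
    if np.allclose(src, tgt):
        return replace(v, spacing=target_spacing)
    new_shape = np.maximum(1, np.round(np.array(v.shape) * src / tgt)).astype(int)
    grids = [((np.arange(n) + 0.5) * t / s) - 0.5
             for n, t, s in zip(new_shape, tgt, src)]
    coords = np.meshgrid(*grids, indexing="ij")
    order = 1 if mode == "linear" else 0
    values = np.asarray(v.values, dtype=float)
    out = ndimage.map_coordinates(values, np.stack(coords), order=order,
                                  mode="nearest")
    if isinstance(v, Mask3D):
        return Mask3D(out > 0.5, target_spacing, v.orientation)
    return replace(v, values=out, spacing=target_spacing)


def clip_normalize_ct(v: Volume3D, hu_window=(-1000.0, 1000.0)) -> Volume3D:
    """Clip CT to an HU window and affinely map it to [−1, 1]."""
    lo, hi = (float(x) for x in hu_window)
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid HU window [{lo}, {hi}]")
    clipped = np.clip(v.values, lo, hi)
    norm = 2.0 * (clipped - lo) / (hi - lo) - 1.0
    return v.with_values(norm, modality=CT_NORM)


def clip_pet_suv(v: Volume3D, suv_max: float = 30.0) -> Volume3D:
    """Clip PET to [0, suv_max]; units stay SUV (metrics live in SUV space)."""
    if suv_max <= 0:
        raise ValueError("suv_max must be positive")
    return v.with_values(np.clip(v.values, 0.0, suv_max), modality=PET_SUV)


def body_mask(ct: Volume3D, threshold_hu: float = -500.0) -> Mask3D:
    """Foreground/body mask: HU above threshold, largest component, holes filled.

    Hole filling keeps the (low-HU) lungs inside the body mask, matching an
    evaluation mask that excludes only air/background outside the patient.
    """
    if ct.modality != CT_HU:
        raise ValueError("body_mask expects a CT-HU volume (pre-normalization)")
    fg = ct.values > threshold_hu
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n == 0:
        raise ValueError("empty body mask: no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    filled = ndimage.binary_fill_holes(largest)
    return Mask3D(filled, ct.spacing, ct.orientation)


def surrogate_lung_mask(ct: Volume3D, threshold_hu: float = -400.0) -> Mask3D:
    """Threshold-based lung segmentation on CT.

    Voxels below ``threshold_hu`` inside the body mask; the two largest
    connected components are kept.  A single-component result warns; an
    empty result warns and returns an empty mask.
    """
    if ct.modality != CT_HU:
        raise ValueError("surrogate_lung_mask expects a CT-HU volume")
    body = body_mask(ct)
    cand = (ct.values < threshold_hu) & body.values
    labels, n = ndimage.label(cand, structure=_CONN26)
    if n == 0:
        warnings.warn("no lung candidate voxels found; returning empty mask")
        return Mask3D(np.zeros(ct.shape, dtype=bool), ct.spacing, ct.orientation)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = order[:2] + 1
    if n < 2:
        warnings.warn("only one lung candidate component found")
    mask = np.isin(labels, keep)
    return Mask3D(mask, ct.spacing, ct.orientation)


def lung_base_crop_bounds(lung_mask: Mask3D) -> CropBounds:
    """Bounds keeping everything from the inferior lung extent to the top.

    The superior axis is the third array axis (RAS convention); in-plane
    axes are untouched at this stage.
    """
    if not lung_mask.values.any():
        raise ValueError("empty lung mask: supply an external lung mask instead")
    z_any = np.nonzero(lung_mask.values.any(axis=(0, 1)))[0]
    z0 = int(z_any.min())
    nx, ny, nz = lung_mask.shape
    return CropBounds(((0, nx), (0, ny), (z0, nz)))


def apply_bounds(v: Volume3D | Mask3D, bounds: CropBounds):
    """Crop a volume or mask to the given half-open index intervals."""
    for (lo, hi), n in zip(bounds.intervals, v.shape):
        if lo < 0 or hi > n:
            raise ValueError(f"crop interval [{lo},{hi}) outside grid of size {n}")
    return replace(v, values=v.values[bounds.slices()])


def fixed_size_crop_pad(v: Volume3D | Mask3D, target_shape=(96, 96, 64),
                        pad_value: float = 0.0):
    """Centre-crop / symmetrically pad each axis to an exact target shape.

    Odd crop or pad remainders go to the far (high-index) side.  Typical pad
    values: −1 for normalized CT (−1000 HU pre-normalization), 0 for PET
    SUV and masks.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError("target shape must be positive")
    data = v.values
    for ax, tgt in enumerate(target_shape):
        n = data.shape[ax]
        if n > tgt:
            lo = (n - tgt) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(lo, lo + tgt)
            data = data[tuple(sl)]
        elif n < tgt:
            before = (tgt - n) // 2
            after = tgt - n - before
            pad = [(0, 0)] * 3
            pad[ax] = (before, after)
            if isinstance(v, Mask3D):
                data = np.pad(data, pad, constant_values=False)
            else:
                data = np.pad(data, pad, constant_values=pad_value)
    return replace(v, values=data)


def preprocess_case(ct: Volume3D, pet: Volume3D,
                    lung_mask: Mask3D | None = None,
                    extra_masks: dict[str, Mask3D] | None = None,
                    target_spacing=(2.0, 2.0, 3.0),
                    target_shape=(96, 96, 64),
                    hu_window=(-1000.0, 1000.0), suv_max: float = 30.0):
    """Full preprocessing pipeline for one paired case.

    Reorients to RAS, resamples, derives body/lung masks on CT, applies the
    lung-base-to-head crop, intensity-normalizes, and crops/pads all
    volumes to ``target_shape``.  Returns a dict with keys ``ct_norm``,
    ``pet``, ``body``, ``lung`` plus any entries of ``extra_masks``.
    """
    ct = reorient_to_ras(ct)
    pet = reorient_to_ras(pet)
    ct = resample(ct, target_spacing, "linear")
    pet = resample(pet, target_spacing, "linear")
    masks: dict[str, Mask3D] = {}
    for name, m in (extra_masks or {}).items():
        masks[name] = resample(reorient_to_ras(m), target_spacing, "nearest")
    if lung_mask is None:
        lung = surrogate_lung_mask(ct)
    else:
        lung = resample(reorient_to_ras(lung_mask), target_spacing, "nearest")
    body = body_mask(ct)
    bounds = lung_base_crop_bounds(lung)

    ct = apply_bounds(ct, bounds)
    pet = apply_bounds(pet, bounds)
    body = apply_bounds(body, bounds)
    lung = apply_bounds(lung, bounds)
    masks = {k: apply_bounds(m, bounds) for k, m in masks.items()}

    ct_norm = clip_normalize_ct(ct, hu_window)
    pet = clip_pet_suv(pet, suv_max)

    out = {
        "ct_norm": fixed_size_crop_pad(ct_norm, target_shape, pad_value=-1.0),
        "pet": fixed_size_crop_pad(pet, target_shape, pad_value=0.0),
        "body": fixed_size_crop_pad(body, target_shape),
        "lung": fixed_size_crop_pad(lung, target_shape),
    }
    for k, m in masks.items():
        out[k] = fixed_size_crop_pad(m, target_shape)
    return out
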