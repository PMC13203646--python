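"""Seeded paired CT/PET phantom generator.

Emulates the anatomical coupling a CT-to-PET translation model relies on,
at desk scale: a body ellipsoid of soft-tissue HU containing two low-HU
lung ellipsoids, spherical hypermetabolic lesions whose SUV is drawn
independently of their (mild) CT correlate, a smooth background uptake
field, additive Gaussian noise, and exactly aligned CT/PET/mask geometry.

Lesions are spheres in world (mm) coordinates rasterized on the voxel grid,
so ground-truth volumes are analytically checkable.  Everything is
bit-reproducible from ``(spec, case_seed)``; cohort per-case seeds are
derived from the cohort seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CT_HU, PET_SUV, Mask3D, Volume3D, save_volume

__all__ = ["PhantomSpec", "generate_case", "generate_cohort", "load_manifest_case"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom cohort.

    HU levels follow the usual CT scale (air −1000, soft tissue ≈ 40,
    aerated lung ≈ −750); uptake is in SUV with a background near 1 and
    hypermetabolic lesions well above it.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    body_hu: float = 40.0
    lung_hu: float = -750.0
    air_hu: float = -1000.0
    lesion_hu_delta: float = 30.0
    background_suv: float = 1.0
    background_cv: float = 0.1
    lung_suv_factor: float = 0.35
    lesion_suv_range: tuple[float, float] = (4.0, 12.0)
    lesion_count_range: tuple[int, int] = (0, 5)
    lesion_radius_range: tuple[float, float] = (4.0, 12.0)
    ct_noise_sd: float = 20.0
    pet_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_suv_range[0] <= self.background_suv:
            raise ValueError("lesion SUV minimum must exceed background SUV")
        for name in ("lesion_suv_range", "lesion_count_range", "lesion_radius_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")


def _ellipsoid(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    terms = ((xx - center_mm[0]) / radii_mm[0]) ** 2 \
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2 \
        + ((zz - center_mm[2]) / radii_mm[2]) ** 2
    return terms <= 1.0


def _smooth_field(rng, shape, sigma_vox=4.0) -> np.ndarray:
    """Zero-mean unit-ish smooth random field for background uptake texture."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_case(spec: PhantomSpec, case_seed: int,
                  max_attempts: int = 200):
    """Generate one paired (CT, PET, lesion mask, lung mask) phantom case.

    Deterministic given ``(spec, case_seed)``.  Lesion spheres are placed
    inside the body without mutual overlap; placement failure after
    ``max_attempts`` draws per lesion raises.
    """
    rng = np.random.default_rng(case_seed)
    shape = spec.grid_shape
    spacing = spec.spacing
    extent = np.array(shape) * np.array(spacing)

    # body ellipsoid spanning nearly the full S axis; semi-axes scaled
    # 0.75-1.0 per axis with in-plane centre jitter (habitus variability)
    body_radii = extent / 2.0 * np.array([0.82, 0.82, 0.95]) \
        * rng.uniform(0.75, 1.0, size=3)
    body_center = extent / 2.0 + np.array([
        rng.uniform(-0.04, 0.04) * extent[0],
        rng.uniform(-0.04, 0.04) * extent[1], 0.0])
    body = _ellipsoid(shape, spacing, body_center, body_radii)

    # two lung ellipsoids in the lower-mid section, leaving a "head" region
    # of body above the lung apex; placed relative to the body geometry so
    # they stay inside it under habitus variation, with per-case jitter
    lung_z = body_center[2] - (0.40 + rng.uniform(-0.05, 0.05)) * body_radii[2]
    lungs = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        radii = body_radii * np.array([0.36, 0.44, 0.40]) \
            * rng.uniform(0.85, 1.1, size=3)
        c = np.array([body_center[0] + side * 0.45 * body_radii[0],
                      body_center[1] + rng.uniform(-0.06, 0.06) * body_radii[1],
                      lung_z])
        lungs |= _ellipsoid(shape, spacing, c, radii)
    # keep a one-voxel pleural margin: lungs stay strictly interior to the
    # body so they are closed cavities (hole filling recovers them)
    lungs &= ndimage.binary_erosion(body)

    # lesions: spheres in mm coordinates, inside the body, non-overlapping
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    lesion_mask = np.zeros(shape, dtype=bool)
    lesion_suvs: list[float] = []
    for _ in range(n_lesions):
        placed = False
        for _attempt in range(max_attempts):
            r = rng.uniform(*spec.lesion_radius_range)
            center = rng.uniform(r, extent - r)
            # sphere entirely inside the body ellipsoid (mm test on the sphere
            # centre with margin r along each body radius)
            if (body_radii <= r + 1e-9).any():
                continue
            margin = (center - body_center) / (body_radii - r)
            if (margin ** 2).sum() > 1.0:
                continue
            sphere = _ellipsoid(shape, spacing, center, (r, r, r))
            # require separation from existing lesions even under
            # 26-connectivity, so components never merge on the voxel grid
            dilated = ndimage.binary_dilation(lesion_mask, np.ones((3, 3, 3)))
            if not sphere.any() or (sphere & dilated).any():
                continue
            lesion_mask |= sphere
            lesion_suvs.append(float(rng.uniform(*spec.lesion_suv_range)))
            # remember per-lesion geometry via labelling order below
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lesion without overlap after {max_attempts} attempts")

    # CT: air outside, soft tissue in body, lung HU in lungs, mild lesion correlate
    ct = np.full(shape, spec.air_hu, dtype=np.float64)
    ct[body] = spec.body_hu
    ct[lungs] = spec.lung_hu
    ct[lesion_mask] += spec.lesion_hu_delta

    # PET: zero outside body, smooth background uptake inside, lesions hot.
    # The bounded smooth field keeps background below lesion_suv_range[0],
    # so every lesion voxel beats every background voxel before noise.
    pet = np.zeros(shape, dtype=np.float64)
    bg = spec.background_suv * (
        1.0 + spec.background_cv * np.tanh(_smooth_field(rng, shape)))
    pet[body] = bg[body]
    # aerated lung takes up far less FDG than soft tissue
    pet[lungs] *= spec.lung_suv_factor
    # assign per-lesion SUV by re-rasterizing in placement order
    labels, n_cc = ndimage.label(lesion_mask, structure=np.ones((3, 3, 3)))
    # placement order and component labels may differ; draw per component
    # from the recorded SUVs by matching counts (components == placements
    # because lesions do not overlap and are spheres)
    for lab in range(1, n_cc + 1):
        suv = lesion_suvs[lab - 1] if lab - 1 < len(lesion_suvs) else \
            float(rng.uniform(*spec.lesion_suv_range))
        pet[labels == lab] = suv

    # additive noise, PET clipped non-negative (SUV is non-negative)
    if spec.ct_noise_sd > 0:
        ct += rng.normal(0.0, spec.ct_noise_sd, shape)
    if spec.pet_noise_sd > 0:
        pet += rng.normal(0.0, spec.pet_noise_sd, shape)
        np.clip(pet, 0.0, None, out=pet)

    ct_v = Volume3D(ct, spacing, "RAS", CT_HU)
    pet_v = Volume3D(pet, spacing, "RAS", PET_SUV)
    return (ct_v, pet_v,
            Mask3D(lesion_mask, spacing, "RAS"),
            Mask3D(lungs, spacing, "RAS"))


def case_seed_for(cohort_seed: int, index: int) -> int:
    """Stable per-case seed derived from the cohort seed."""
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


MANIFEST_COLUMNS = ["case_id", "ct_path", "pet_path", "lesion_path",
                    "lung_path", "seed", "n_lesions"]


def generate_cohort(spec: PhantomSpec, n: int, seed: int,
                    out_dir: str | Path, force: bool = False) -> pd.DataFrame:
    """Write ``n`` phantom cases as NIfTI plus a CSV manifest; return the manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    rows = []
    for i in range(n):
        cs = case_seed_for(seed, i)
        ct, pet, lesions, lungs = generate_case(spec, cs)
        cid = f"case_{i:04d}"
        paths = {k: out_dir / f"{cid}_{k}.nii.gz"
                 for k in ("ct", "pet", "lesion", "lung")}
        save_volume(ct, paths["ct"])
        save_volume(pet, paths["pet"])
        save_volume(lesions, paths["lesion"])
        save_volume(lungs, paths["lung"])
        n_cc = int(ndimage.label(lesions.values, structure=np.ones((3, 3, 3)))[1])
        rows.append([cid, str(paths["ct"]), str(paths["pet"]),
                     str(paths["lesion"]), str(paths["lung"]), cs, n_cc])
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def load_manifest_case(row) -> tuple[Volume3D, Volume3D, Mask3D, Mask3D]:
    """Load one manifest row back into in-memory volumes."""
    from .core import load_mask, load_volume

    return (load_volume(row["ct_path"], CT_HU),
            load_volume(row["pet_path"], PET_SUV),
            load_mask(row["lesion_path"]),
            load_mask(row["lung_path"]))
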