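"""Synthetic CT phantoms, threshold segmentation, and the volume ratio (VRM).

An air-filled sinus cavity on CT sits near −1000 HU inside bone near +700 HU,
so a cavity can be delineated by thresholding (everything at or below
−400 HU) and taking the connected component around a seed voxel — the same
principle as semiautomatic region-growing segmentation in clinical tools.
The phantoms here are ellipsoidal cavities in a bone-valued grid, optionally
filled with soft tissue (an opacified sinus, which thresholding at −400 HU
deliberately cannot capture) and perturbed by Gaussian HU noise.

The volume ratio measure (VRM) makes segmented volumes comparable with the
diameter ratio: cube roots bring volumes to diameter-like units, their mean
is divided by the mean reference diameter, and the per-scan VRM series feeds
the same per-patient slope fit as the DRM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    GeometryError,
    InsufficientDataError,
    SeedOutsideCavityError,
    ValidationError,
)

#: Clinical segmentation threshold: a voxel at or below this HU is cavity.
DEFAULT_UPPER_THRESHOLD_HU = -400.0


@dataclass(frozen=True)
class Cavity:
    """One ellipsoidal cavity: centre in voxel coordinates, semi-axes in mm."""

    sinus: str
    center_voxel: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    filled: bool = False  # True = opacified (soft tissue instead of air)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError(f"semi-axes must be positive, got {self.semi_axes_mm}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and HU levels of one synthetic CT volume."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    cavities: tuple[Cavity, ...] = ()
    background_hu: float = 700.0   # cortical-bone-like
    cavity_hu: float = -1000.0     # air
    soft_tissue_hu: float = 40.0   # mucosa / opacification
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValidationError("voxel_size_mm must be positive")
        if self.noise_sd_hu < 0:
            raise ValidationError("noise_sd_hu must be >= 0")
        for c in self.cavities:
            for axis in range(3):
                r_vox = c.semi_axes_mm[axis] / self.voxel_size_mm
                lo = c.center_voxel[axis] - r_vox
                hi = c.center_voxel[axis] + r_vox
                if lo < 0 or hi > self.grid_shape[axis] - 1:
                    raise GeometryError(
                        f"cavity {c.sinus!r} exceeds grid bounds on axis {axis}")


def ellipsoid_volume_mm3(semi_axes_mm: Sequence[float]) -> float:
    """Analytic ellipsoid volume (4/3)·π·a·b·c in mm³."""
    a, b, c = semi_axes_mm
    return 4.0 / 3.0 * math.pi * a * b * c


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a PhantomSpec to a float32 HU volume, deterministically per seed."""
    vol = np.full(spec.grid_shape, spec.background_hu, dtype=np.float32)
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    for c in spec.cavities:
        terms = []
        for axis in range(3):
            r_vox = c.semi_axes_mm[axis] / spec.voxel_size_mm
            terms.append(((grids[axis] - c.center_voxel[axis]) / r_vox) ** 2)
        inside = terms[0] + terms[1] + terms[2] <= 1.0
        vol[inside] = spec.soft_tissue_hu if c.filled else spec.cavity_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape).astype(np.float32)
    return vol


def segment_cavity(volume: np.ndarray, seed_point: tuple[int, int, int],
                   upper_threshold_hu: float = DEFAULT_UPPER_THRESHOLD_HU
                   ) -> np.ndarray:
    """Region-grow the cavity containing ``seed_point``.

    The mask is the 26-connected component of {voxel : HU <= threshold} that
    contains the seed.  The threshold is inclusive: a voxel at exactly
    −400 HU belongs to the cavity.

    Raises
    ------
    SeedOutsideCavityError
        If the seed voxel's HU is above the threshold (e.g. solid bone, or an
        opacified sinus whose soft-tissue filling sits well above −400 HU).
    """
    seed_point = tuple(int(i) for i in seed_point)
    if any(not 0 <= i < n for i, n in zip(seed_point, volume.shape)):
        raise ValidationError(f"seed point {seed_point} outside grid {volume.shape}")
    below = volume <= upper_threshold_hu
    if not below[seed_point]:
        raise SeedOutsideCavityError(
            f"seed voxel {seed_point} has {float(volume[seed_point]):.0f} HU, "
            f"above the {upper_threshold_hu:g} HU threshold")
    labels, _ = ndimage.label(below, structure=np.ones((3, 3, 3), dtype=int))
    return labels == labels[seed_point]


def mask_volume_mm3(mask: np.ndarray, voxel_size_mm: float) -> float:
    """Volume of a binary mask: voxel count × voxel size cubed."""
    if voxel_size_mm <= 0:
        raise ValidationError("voxel_size_mm must be positive")
    return float(np.count_nonzero(mask)) * float(voxel_size_mm) ** 3


@dataclass(frozen=True)
class SinusVolumeRecord:
    """One sinus volume with the method that produced it."""

    sinus: str
    volume_mm3: float
    method: str = "threshold_segmentation"  # or "analytic"

    def __post_init__(self) -> None:
        if not math.isfinite(self.volume_mm3) or self.volume_mm3 < 0:
            raise ValidationError(f"volume must be finite and >= 0, got {self.volume_mm3!r}")
        if self.method not in ("threshold_segmentation", "analytic", "manual"):
            raise ValidationError(f"unknown volume method {self.method!r}")


def compute_vrm(volumes_mm3: Sequence[float], references_mm: Sequence[float]
                ) -> float:
    """Volume ratio measure: mean cube root of the sinus volumes divided by
    the mean reference diameter.  Missing entries are passed as None (or an
    empty sequence); at least one volume and one reference are required.

    Like the DRM, the VRM is invariant to a common size rescaling: volumes
    scaled by k³ and references by k leave it unchanged.
    """
    vols = [v for v in volumes_mm3 if v is not None]
    refs = [r for r in references_mm if r is not None]
    if not vols:
        raise InsufficientDataError("no sinus volumes present")
    if not refs:
        raise InsufficientDataError("no reference measurements present")
    for v in vols:
        if not math.isfinite(v) or v < 0:
            raise ValidationError(f"volume must be finite and >= 0, got {v!r}")
    for r in refs:
        if not math.isfinite(r) or r <= 0:
            raise ValidationError(f"reference must be positive, got {r!r}")
    mean_cbrt = sum(v ** (1.0 / 3.0) for v in vols) / len(vols)
    return mean_cbrt / (sum(refs) / len(refs))


def vrm_table(volumes, references):
    """Per-scan VRM table from tidy volume and reference tables.

    ``volumes``: columns patient_id, scan_date, sinus, volume_mm3.
    ``references``: columns patient_id, scan_date, axial_ref_mm, coronal_ref_mm.
    Returns columns patient_id, scan_date, vrm.
    """
    import pandas as pd

    vols = pd.DataFrame(volumes)
    refs = pd.DataFrame(references)
    rows = []
    ref_idx = refs.set_index(["patient_id", "scan_date"])
    for (pid, when), g in vols.groupby(["patient_id", "scan_date"], sort=True):
        r = ref_idx.loc[(pid, when)]
        rows.append((pid, when, compute_vrm(
            list(g["volume_mm3"]),
            [r["axial_ref_mm"], r["coronal_ref_mm"]])))
    return pd.DataFrame(rows, columns=["patient_id", "scan_date", "vrm"])


# ---------------------------------------------------------------------------
# NIfTI I/O — voxel size carried in the header zooms.

def save_nifti(path, volume: np.ndarray, voxel_size_mm: float) -> None:
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        raise ValidationError(f"anisotropic voxels {zooms} not supported")
    return np.asarray(img.dataobj), float(zooms[0])
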