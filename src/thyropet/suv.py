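"""SUV metrics for an index nodule.

SUVmax is the hottest voxel in the nodule region; SUVpeak is the maximum mean
uptake over a 1 cm^3 sphere (diameter ~12.4 mm) centred on any voxel whose
sphere touches the region; the background SUVmax is taken in the contralateral
thyroid lobe; the two SUV-ratios divide nodule SUVmax/SUVpeak by that
background. Input volumes are assumed body-weight-normalised SUV (g/mL)
already — no activity-to-SUV conversion happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, VoiMask

#: Radius (mm) of a sphere of volume 1 mL: (3/(4*pi) * 1000 mm^3)^(1/3)
PEAK_SPHERE_RADIUS_MM = (3.0 / (4.0 * math.pi) * 1000.0) ** (1.0 / 3.0)


@dataclass
class SuvReport:
    """SUV metrics for one nodule (all in g/mL; ratios dimensionless)."""

    suv_max: float
    suv_peak: float
    background_suv_max: float

    def __post_init__(self) -> None:
        if min(self.suv_max, self.suv_peak, self.background_suv_max) <= 0:
            raise ValueError("SUVs must be positive")
        if self.suv_peak > self.suv_max + 1e-9:
            raise ValueError("SUVpeak cannot exceed SUVmax")

    @property
    def suv_max_ratio(self) -> float:
        return self.suv_max / self.background_suv_max

    @property
    def suv_peak_ratio(self) -> float:
        return self.suv_peak / self.background_suv_max

    def rounded(self, decimals: int = 1) -> dict:
        """Presentation values at tabular precision."""
        return {
            "suv_max": round(self.suv_max, decimals),
            "suv_peak": round(self.suv_peak, decimals),
            "background_suv_max": round(self.background_suv_max, decimals),
            "suv_max_ratio": round(self.suv_max_ratio, decimals),
            "suv_peak_ratio": round(self.suv_peak_ratio, decimals),
        }


def _check_aligned(pet: ImageVolume, region: VoiMask) -> None:
    if pet.data.shape != region.data.shape or not np.allclose(pet.spacing, region.spacing):
        raise ValueError("region mask is not aligned to the PET grid")
    if region.voxel_count == 0:
        raise ValueError("empty region")


def compute_suvmax(pet: ImageVolume, region: VoiMask) -> float:
    """Maximum voxel SUV within the region."""
    _check_aligned(pet, region)
    return float(pet.data[region.data].max())


def sphere_kernel(spacing, radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> np.ndarray:
    """Binary kernel of voxels whose centres lie within ``radius_mm``."""
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(radius_mm / spacing).astype(int)
    if np.any(2 * half + 1 <= 1) and np.any(spacing > 2 * radius_mm):
        raise ValueError("grid coarser than the SUVpeak sphere diameter")
    grids = np.indices(2 * half + 1).astype(float)
    r2 = sum(((grids[a] - half[a]) * spacing[a]) ** 2 for a in range(3))
    return r2 <= radius_mm**2


def compute_suvpeak(
    pet: ImageVolume, region: VoiMask, radius_mm: float = PEAK_SPHERE_RADIUS_MM
) -> float:
    """Maximum mean SUV over a 1 mL sphere.

    Candidate sphere centres are voxel centres whose sphere intersects the
    region; sphere membership is by voxel-centre inclusion. Near the volume
    edge the mean is taken over the in-volume part of the sphere.
    """
    _check_aligned(pet, region)
    kernel = sphere_kernel(pet.spacing, radius_mm)
    if kernel.sum() == 0:
        raise ValueError("grid coarser than the SUVpeak sphere diameter")
    k = kernel.astype(float)
    sums = ndimage.correlate(pet.data, k, mode="constant", cval=0.0)
    counts = ndimage.correlate(np.ones_like(pet.data), k, mode="constant", cval=0.0)
    means = sums / counts
    candidates = ndimage.binary_dilation(region.data, structure=kernel)
    return float(means[candidates].max())


def compute_background(
    pet: ImageVolume, contralateral_region: VoiMask, nodule_mask: VoiMask | None = None
) -> float:
    """Background SUVmax of normal thyroid tissue in the contralateral lobe."""
    _check_aligned(pet, contralateral_region)
    if nodule_mask is not None and np.any(contralateral_region.data & nodule_mask.data):
        raise ValueError("background region overlaps the nodule mask")
    return float(pet.data[contralateral_region.data].max())


def mirrored_background_box(region: VoiMask, axis: int = 0, pad_voxels: int = 1) -> VoiMask:
    """Background box mirrored through the volume centre along ``axis``.

    Used in phantom mode, where the nodule sits in one lobe and the mirrored
    box samples the contralateral lobe. The box is the nodule's bounding box
    (padded) reflected about the grid centre plane.
    """
    idx = np.argwhere(region.data)
    lo = np.maximum(idx.min(axis=0) - pad_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + pad_voxels, np.asarray(region.shape) - 1)
    n = region.shape[axis]
    m_lo, m_hi = n - 1 - hi[axis], n - 1 - lo[axis]
    out = np.zeros(region.shape, dtype=bool)
    sl = [slice(lo[a], hi[a] + 1) for a in range(3)]
    sl[axis] = slice(m_lo, m_hi + 1)
    out[tuple(sl)] = True
    out &= ~region.data  # never sample the nodule itself
    if not out.any():
        raise ValueError("mirrored background box is empty (nodule crosses midline?)")
    return VoiMask(out, region.spacing, region.origin, provenance={"kind": "mirrored_box"})


def compute_ratios(suv_max: float, suv_peak: float, background: float) -> tuple[float, float]:
    """SUVmax-ratio and SUVpeak-ratio against the contralateral background."""
    if background <= 0:
        raise ValueError("background SUVmax must be positive")
    return suv_max / background, suv_peak / background


def quantify_nodule(
    pet: ImageVolume, region: VoiMask, background_region: VoiMask | None = None
) -> SuvReport:
    """Full SUV report for one nodule; background box mirrored if not given."""
    if background_region is None:
        background_region = mirrored_background_box(region)
    return SuvReport(
        suv_max=compute_suvmax(pet, region),
        suv_peak=min(compute_suvpeak(pet, region), compute_suvmax(pet, region)),
        background_suv_max=compute_background(pet, background_region, nodule_mask=region),
    )
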