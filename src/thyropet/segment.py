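"""Background-corrected isocontour segmentation of the nodule VOI.

The VOI is delineated on PET with a threshold at 50% of SUVpeak corrected for
local background activity, inside an axis-aligned box that excludes
surrounding FDG-avid tissue; the ldCT VOI is derived from the PET VOI by
nearest-neighbour resampling.

Two published formalisations of "50% of SUVpeak corrected for background"
exist; both are provided:

* ``"relative"`` (default): ``T = bg + 0.5 * (SUVpeak - bg)`` — 50% of the
  background-subtracted peak, added back onto the background;
* ``"additive"``: ``T = 0.5 * SUVpeak + bg``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .suv import compute_suvpeak
from .volumes import ImageVolume, VoiMask

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def apply_boxing(
    pet: ImageVolume, centre_mm, extent_mm, margin_factor: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned crop bounds around a nodule locator.

    ``extent_mm`` is the approximate nodule size (e.g. ultrasound diameter),
    padded by ``margin_factor``; returns inclusive (lo, hi) voxel indices,
    clipped to the volume with a warning if the box sticks out.
    """
    centre_idx = pet.index_of(np.asarray(centre_mm, dtype=float))
    if np.any(centre_idx < -0.5) or np.any(centre_idx > np.asarray(pet.shape) - 0.5):
        raise ValueError("locator centre lies outside the volume")
    half = margin_factor * np.broadcast_to(np.asarray(extent_mm, dtype=float), (3,)) / 2.0
    lo = np.floor(centre_idx - half / pet.spacing).astype(int)
    hi = np.ceil(centre_idx + half / pet.spacing).astype(int)
    if np.any(lo < 0) or np.any(hi > np.asarray(pet.shape) - 1):
        warnings.warn("boxing clipped to the volume bounds", stacklevel=2)
    lo = np.clip(lo, 0, np.asarray(pet.shape) - 1)
    hi = np.clip(hi, 0, np.asarray(pet.shape) - 1)
    return lo, hi


def _box_mask(shape, lo, hi) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return out


def isocontour_threshold(suv_peak: float, background_suv: float, mode: str = "relative") -> float:
    """Background-corrected 50%-of-SUVpeak threshold."""
    if mode == "relative":
        return background_suv + 0.5 * (suv_peak - background_suv)
    if mode == "additive":
        return 0.5 * suv_peak + background_suv
    raise ValueError(f"unknown threshold mode {mode!r}")


def segment_nodule(
    pet: ImageVolume,
    box: tuple[np.ndarray, np.ndarray],
    background_suv: float,
    mode: str = "relative",
) -> VoiMask:
    """Delineate the nodule VOI by background-corrected isocontour.

    SUVpeak is computed within the box; voxels in the box at or above the
    threshold are kept and reduced to the single 26-connected component
    containing the in-box SUVmax voxel. Provenance records the threshold.
    """
    if background_suv < 0:
        raise ValueError("background SUV must be non-negative")
    lo, hi = (np.asarray(b, dtype=int) for b in box)
    if np.any(hi < lo):
        raise ValueError("empty box")
    box_arr = _box_mask(pet.shape, lo, hi)
    box_voi = VoiMask(box_arr, pet.spacing, pet.origin)
    suv_peak = compute_suvpeak(pet, box_voi)
    if suv_peak <= background_suv:
        raise ValueError("nodule not above background (SUVpeak <= background)")
    threshold = isocontour_threshold(suv_peak, background_suv, mode)

    above = box_arr & (pet.data >= threshold)
    if not above.any():
        raise ValueError("empty mask at the isocontour threshold")
    in_box = np.where(box_arr, pet.data, -np.inf)
    seed = np.unravel_index(np.argmax(in_box), pet.shape)
    labels, _ = ndimage.label(above, structure=_STRUCT26)
    component = labels[seed]
    if component == 0:
        # SUVmax voxel below threshold cannot happen (max >= peak >= T when
        # peak > bg), but guard against degenerate numeric input
        raise ValueError("SUVmax voxel not above threshold")
    mask = labels == component
    return VoiMask(
        mask,
        pet.spacing,
        pet.origin,
        provenance={
            "threshold": float(threshold),
            "suv_peak": float(suv_peak),
            "background_suv": float(background_suv),
            "mode": mode,
            "box_lo": lo.tolist(),
            "box_hi": hi.tolist(),
        },
    )


def resample_mask(mask: VoiMask, target_spacing, target_shape=None, target_origin=None) -> VoiMask:
    """Nearest-neighbour resampling of a mask onto a target grid.

    Grids share the world frame; each target voxel takes the value of the
    nearest source voxel centre. Default target extent covers the source
    field of view starting at the source origin.
    """
    target_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,)).copy()
    if np.any(target_spacing <= 0):
        raise ValueError("non-positive target spacing")
    if target_origin is None:
        target_origin = mask.origin.copy()
    else:
        target_origin = np.asarray(target_origin, dtype=float)
    if target_shape is None:
        extent = np.asarray(mask.shape) * mask.spacing
        target_shape = np.maximum(np.round(extent / target_spacing), 1).astype(int)
    target_shape = tuple(int(s) for s in target_shape)

    idx = np.indices(target_shape, dtype=float)
    world = [target_origin[a] + idx[a] * target_spacing[a] for a in range(3)]
    src = [np.round((world[a] - mask.origin[a]) / mask.spacing[a]).astype(int) for a in range(3)]
    inside = np.ones(target_shape, dtype=bool)
    for a in range(3):
        inside &= (src[a] >= 0) & (src[a] < mask.shape[a])
    if not inside.any():
        raise ValueError("target grid does not overlap the mask field of view")
    out = np.zeros(target_shape, dtype=bool)
    sel = tuple(np.clip(src[a], 0, mask.shape[a] - 1) for a in range(3))
    out[inside] = mask.data[sel][inside]
    return VoiMask(
        out,
        target_spacing,
        target_origin,
        provenance={**mask.provenance, "resampled_from_spacing": mask.spacing.tolist()},
    )


def check_min_voxels(mask: VoiMask, minimum: int = 64) -> bool:
    """True iff the VOI meets the minimal-size recommendation (>= 64 voxels)."""
    return mask.voxel_count >= minimum
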