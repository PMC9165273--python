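"""Standardised radiomic feature extraction (IBSI-aligned catalogue).

107 features per modality: 14 shape, 18 first-order intensity and 75 texture
(24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM); PET additionally carries the
total lesion glycolysis (TLG = SUVmean x metabolic tumour volume). The name
catalogue is frozen in :data:`FEATURE_MANIFEST` — any drift in count or
naming fails the golden-manifest test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volumes import ImageVolume, VoiMask
from .firstorder import FIRSTORDER_FEATURE_NAMES, firstorder_features
from .preprocess import (
    CT_BIN_WIDTH,
    CT_TARGET_SPACING_MM,
    PET_BIN_WIDTH,
    PET_TARGET_SPACING_MM,
    discretise,
    interpolate_volume,
)
from .shape import SHAPE_FEATURE_NAMES, shape_features
from .texture import (
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

#: family -> ordered feature names; 14/18/24/16/16/14/5 = 107 per modality
FEATURE_MANIFEST: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURE_NAMES,
    "firstorder": FIRSTORDER_FEATURE_NAMES,
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "gldm": GLDM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
}

ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FEATURE_MANIFEST.items() for name in names
)

N_FEATURES_PER_MODALITY = len(ALL_FEATURE_NAMES)  # 107


@dataclass
class FeatureVector:
    """Named radiomic features for one VOI and modality."""

    values: dict[str, float]
    modality: str
    bin_width: float
    spacing_mm: tuple[float, float, float]
    extras: dict[str, float] = field(default_factory=dict)  # e.g. TLG for PET

    def as_series(self, prefix: str | None = None):
        import pandas as pd

        prefix = prefix if prefix is not None else f"{self.modality}_"
        data = {f"{prefix}{k}": v for k, v in {**self.values, **self.extras}.items()}
        return pd.Series(data)


def extract_features(
    vol: ImageVolume,
    mask: VoiMask,
    modality: str = "PET",
    bin_width: float | None = None,
    families: tuple[str, ...] | None = None,
) -> FeatureVector:
    """Extract the standardised feature set from an (already interpolated) VOI.

    Texture features on a single-voxel mask are undefined and returned as NaN,
    never silently zero. ``families`` restricts extraction (default: all).
    """
    if not mask.data.any():
        raise ValueError("empty mask")
    if vol.data.shape != mask.data.shape:
        raise ValueError("volume and mask grids differ")
    if bin_width is None:
        bin_width = PET_BIN_WIDTH if modality.upper() == "PET" else CT_BIN_WIDTH
    families = tuple(FEATURE_MANIFEST) if families is None else families

    levels, _ = discretise(vol, mask, bin_width)
    in_mask_levels = levels[mask.data]
    n_levels = int(levels.max())
    values: dict[str, float] = {}
    voxel_volume_mm3 = float(np.prod(vol.spacing))

    for family in families:
        if family == "shape":
            feats = shape_features(mask)
        elif family == "firstorder":
            feats = firstorder_features(vol.data[mask.data], in_mask_levels, voxel_volume_mm3)
        elif family == "glcm":
            feats = glcm_features(levels, n_levels)
        elif family == "glrlm":
            feats = glrlm_features(levels, n_levels)
        elif family == "glszm":
            feats = glszm_features(levels, n_levels)
        elif family == "gldm":
            feats = gldm_features(levels, n_levels=n_levels)
        elif family == "ngtdm":
            feats = ngtdm_features(levels, n_levels)
        else:
            raise ValueError(f"unknown feature family {family!r}")
        values.update({f"{family}_{k}": float(v) for k, v in feats.items()})

    fv = FeatureVector(
        values=values,
        modality=modality.upper(),
        bin_width=float(bin_width),
        spacing_mm=tuple(float(s) for s in vol.spacing),
    )
    return fv


def compute_tlg(pet: ImageVolume, mask: VoiMask) -> float:
    """Total lesion glycolysis: SUVmean x metabolic tumour volume (mL) -> g."""
    if not mask.data.any():
        raise ValueError("empty mask")
    suv_mean = float(pet.data[mask.data].mean())
    mtv_ml = mask.voxel_count * float(np.prod(pet.spacing)) / 1000.0
    return suv_mean * mtv_ml


__all__ = [
    "ALL_FEATURE_NAMES",
    "CT_BIN_WIDTH",
    "CT_TARGET_SPACING_MM",
    "FEATURE_MANIFEST",
    "FeatureVector",
    "N_FEATURES_PER_MODALITY",
    "PET_BIN_WIDTH",
    "PET_TARGET_SPACING_MM",
    "compute_tlg",
    "discretise",
    "extract_features",
    "interpolate_volume",
]
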