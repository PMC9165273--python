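"""Axis-aligned 3-D scalar volumes and binary masks.

PET volumes carry standardised uptake values (SUV, g/mL); CT volumes carry
Hounsfield units. Grids are axis-aligned: a voxel index ``(i, j, k)`` maps to
the world coordinate ``origin + index * spacing`` (voxel centres). No oblique
orientations — the synthetic cohort and every downstream operation work on
plain RAS-aligned grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class ImageVolume:
    """A 3-D scalar grid (PET in g/mL or CT in HU) with voxel geometry.

    Parameters
    ----------
    data
        3-D float array, index order (x, y, z).
    spacing
        Voxel spacing in mm per axis, all > 0.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.full(3, float(self.spacing))
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values (mm)")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_coordinates(self, index: np.ndarray) -> np.ndarray:
        """World position (mm) of the voxel-centre at (fractional) index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def index_of(self, world: np.ndarray) -> np.ndarray:
        """Fractional index of a world coordinate (mm)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing


@dataclass
class VoiMask:
    """Binary volume-of-interest mask on a stated grid.

    ``provenance`` records how the mask was produced (segmentation threshold,
    box bounds) so written masks stay auditable.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.full(3, float(self.spacing))
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive values (mm)")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_nifti(vol: ImageVolume | VoiMask, path: str | Path) -> None:
    data = vol.data.astype(np.uint8) if isinstance(vol, VoiMask) else vol.data
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def load_nifti(path: str | Path, as_mask: bool = False) -> ImageVolume | VoiMask:
    img = nib.load(str(path))
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    data = np.asanyarray(img.dataobj)
    if as_mask:
        return VoiMask(data > 0, spacing, origin)
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)
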