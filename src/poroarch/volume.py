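"""Core voxel-volume containers shared by every analysis stage.

Axis convention throughout the package: ``(z, y, x)`` — axis 0 indexes the
tomographic slice, axis 1 the in-slice row, axis 2 the in-slice column.

Phase convention: in a :class:`VoxelVolume` mask, ``True`` marks material
(bone or ceramic) and ``False`` marks pore space.  Every porosity figure in
the package is derived from the complement of the single canonical mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class UndefinedResultError(ValueError):
    """Raised when a quantity is mathematically undefined for the input
    (e.g. pore thickness of a volume with no pore voxels) rather than zero."""


@dataclass
class GrayVolume:
    """A grayscale tomographic stack with isotropic voxel size in microns."""

    voxels: np.ndarray          # 3D, integer or float intensities
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class VoxelVolume:
    """A binarized volume: ``mask`` is True on material, False on pore."""

    mask: np.ndarray            # 3D boolean
    voxel_size_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        if min(self.mask.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.mask.shape}")
        if not self.voxel_size_um > 0:
            raise ValueError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.size)

    @property
    def n_material(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def n_pore(self) -> int:
        return self.n_voxels - self.n_material

    def pore_mask(self) -> np.ndarray:
        """The pore phase (complement of the material mask)."""
        return ~self.mask

    def inverted(self) -> "VoxelVolume":
        """Swap the material and pore phases (used by symmetry checks)."""
        return VoxelVolume(~self.mask, self.voxel_size_um,
                           provenance=self.provenance + " [phase-inverted]")


@dataclass
class RoiSpec:
    """A square-prism region of interest in physical units.

    ``side_mm`` is the in-slice square side, ``height_mm`` the analyzed
    height along z, ``origin`` the (z, y, x) voxel offset of the ROI corner.
    """

    side_mm: float
    height_mm: float
    origin: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not self.side_mm > 0:
            raise ValueError("side_mm must be > 0")
        if not self.height_mm > 0:
            raise ValueError("height_mm must be > 0")

    def to_voxels(self, voxel_size_um: float) -> tuple[int, int]:
        """Return (height_vox, side_vox) by nearest-integer rounding of
        mm / voxel size.  5 mm at 4.95 um/voxel -> 1010 voxels."""
        side = int(round(self.side_mm * 1000.0 / voxel_size_um))
        height = int(round(self.height_mm * 1000.0 / voxel_size_um))
        return height, side
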