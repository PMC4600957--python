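"""Reading and writing tomographic slice stacks, binarization and ROI cut.

Slice stacks are directories with one 2D image per slice (TIFF/PNG/BMP).
Slices are stacked along z in plain lexicographic filename order by
default, so ``s10`` sorts before ``s2``; pass ``natural_sort=True`` to
order by embedded integers instead.  Masks on disk are 8-bit {0, 255}
with 255 = material.
"""

from __future__ import annotations

import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .volume import GrayVolume, RoiSpec, VoxelVolume


def _natural_key(name: str) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in re.split(r"(\d+)", name))


def read_slice_stack(directory: str | Path, pattern: str = "*",
                     voxel_size_um: float = 4.95,
                     natural_sort: bool = False) -> GrayVolume:
    """Read a directory of 2D slice images into a :class:`GrayVolume`.

    Parameters
    ----------
    directory, pattern
        Directory and filename glob selecting the slice files.
    voxel_size_um
        Edge length of the (isotropic) voxel in microns.
    natural_sort
        If True, order files by embedded integers (s2 before s10);
        default is plain lexicographic order.

    Raises
    ------
    FileNotFoundError
        If no file matches the pattern.
    ValueError
        If slice shapes disagree (the offending file is named).
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern),
                   key=(lambda p: _natural_key(p.name)) if natural_sort
                   else (lambda p: p.name))
    files = [f for f in files if f.is_file()]
    if not files:
        raise FileNotFoundError(
            f"no slice files matching {pattern!r} in {directory}")
    slices = []
    shape0 = None
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:            # RGB(A) slice: keep first channel
            img = img[..., 0]
        if shape0 is None:
            shape0 = img.shape
        elif img.shape != shape0:
            raise ValueError(
                f"slice shape mismatch: {f.name} has {img.shape}, "
                f"expected {shape0}")
        slices.append(img)
    return GrayVolume(np.stack(slices, axis=0), voxel_size_um)


def write_slice_stack(vol: GrayVolume | VoxelVolume, directory: str | Path,
                      prefix: str = "slice", ext: str = "tif") -> list[Path]:
    """Write a volume as one image per slice; masks become 8-bit {0,255}.

    Filenames are zero-padded so lexicographic order equals slice order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, VoxelVolume):
        data = np.where(vol.mask, np.uint8(255), np.uint8(0))
    else:
        data = vol.voxels
    ndigits = max(4, len(str(data.shape[0])))
    paths = []
    for z in range(data.shape[0]):
        p = directory / f"{prefix}_{z:0{ndigits}d}.{ext}"
        if ext.lower() in ("tif", "tiff"):
            tifffile.imwrite(p, data[z])
        else:
            iio.imwrite(p, data[z])
        paths.append(p)
    return paths


def global_threshold(vol: GrayVolume, threshold: float) -> VoxelVolume:
    """Binarize by a single global threshold: material where
    intensity >= threshold (inclusive on the material side)."""
    mask = vol.voxels >= threshold
    return VoxelVolume(mask, vol.voxel_size_um,
                       provenance=f"global_threshold(>= {threshold})")


def extract_roi(vol: VoxelVolume, roi: RoiSpec) -> VoxelVolume:
    """Cut the analysis ROI (square side x height, mm) out of a volume.

    mm -> voxel conversion rounds to the nearest integer; the realized ROI
    in voxels is recorded in the provenance string.
    """
    height, side = roi.to_voxels(vol.voxel_size_um)
    z0, y0, x0 = roi.origin
    ends = (z0 + height, y0 + side, x0 + side)
    overflow = [max(0, e - s) for e, s in zip(ends, vol.shape)]
    if any(o > 0 for o in overflow) or min(z0, y0, x0) < 0:
        raise ValueError(
            f"ROI exceeds volume bounds: overflow (z,y,x) = {tuple(overflow)} "
            f"for origin {roi.origin}, extent ({height},{side},{side}) in "
            f"volume {vol.shape}")
    sub = vol.mask[z0:z0 + height, y0:y0 + side, x0:x0 + side]
    prov = (vol.provenance +
            f" | roi origin={roi.origin} extent_vox=({height},{side},{side})"
            f" from ({roi.height_mm} mm, {roi.side_mm} mm)")
    return VoxelVolume(sub.copy(), vol.voxel_size_um, provenance=prov)
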