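"""3D microarchitecture parameters of a binarized volume.

Three parameters characterize the porous microarchitecture of a bone core
or granule stack, following standard bone-morphometry nomenclature:

* Po (%) — porosity, the pore-voxel fraction of the total volume TV;
* BS/TV (mm²/mm³) — specific surface, the material/pore interface area
  per unit total volume.  The interface is measured on a triangulated
  iso-surface at the 0.5 level of the binary mask (marching cubes);
  voxel-face counting would overestimate oblique interfaces by up to
  ~50%.  Faces where the material is cut by the ROI boundary are not an
  interface and are excluded (the iso-surface is simply left open there);
* Po·Diam (μm) — mean pore diameter by sphere fitting: each pore voxel is
  assigned the diameter of the largest sphere fully contained in the
  pore phase that covers it (local thickness), and the volume-weighted
  mean over pore voxels is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import UndefinedResultError, VoxelVolume


@dataclass
class MorphometryResult:
    """Morphometry of one sample: Po (%), BS (mm²), TV (mm³),
    BS/TV (mm²/mm³), volume-weighted mean pore diameter (μm) and the pore
    thickness histogram (bin edges in μm, pore-volume fraction per bin)."""

    Po: float
    BS: float
    TV: float
    BS_TV: float
    PoDiam_mean: float
    thickness_histogram: tuple[np.ndarray, np.ndarray]

    def to_dict(self) -> dict:
        return {"Po": self.Po, "BS": self.BS, "TV": self.TV,
                "BS_TV": self.BS_TV, "PoDiam_mean": self.PoDiam_mean}


def compute_porosity(vol: VoxelVolume) -> float:
    """Porosity in percent: 100 × pore voxels / total voxels.

    Counting is integer-exact before the single division, so a volume and
    its phase inversion sum to exactly 100.
    """
    return 100.0 * vol.n_pore / vol.n_voxels


def compute_surface_density(vol: VoxelVolume,
                            smooth_sigma: float = 0.8) -> float:
    """Specific surface BS/TV in mm²/mm³ from a marching-cubes iso-surface.

    The binary mask is meshed at the 0.5 iso-level; because the volume is
    not padded, no surface is generated where a phase is cut by the ROI
    boundary, which excludes the (non-interface) cut faces.  The result is
    symmetric under phase inversion.  ``smooth_sigma`` optionally smooths
    the mask (Gaussian, in voxels) before meshing to reduce voxelization
    bias on curved interfaces; 0 meshes the raw binary mask.  The default
    of 0.8 voxels brings a voxelized sphere's area within ~0.5% of 4πr²
    (the raw binary mesh overestimates it by ~9%) while leaving flat
    interfaces unchanged.
    """
    mask = vol.mask.astype(np.float32)
    if smooth_sigma > 0:
        mask = ndimage.gaussian_filter(mask, smooth_sigma)
    if mask.min() >= 0.5 or mask.max() < 0.5:
        return 0.0                       # uniform volume: no interface
    spacing_mm = vol.voxel_size_um / 1000.0
    verts, faces, _, _ = measure.marching_cubes(
        mask, level=0.5, spacing=(spacing_mm,) * 3)
    bs_mm2 = float(measure.mesh_surface_area(verts, faces))
    tv_mm3 = vol.n_voxels * spacing_mm ** 3
    return bs_mm2 / tv_mm3


def local_thickness(pore: np.ndarray, max_levels: int = 64) -> np.ndarray:
    """Sphere-fitting local thickness of the True phase, in voxels.

    For a sphere centered at voxel c, the inscribed radius is
    r(c) = EDT(c), the Euclidean distance from c to the nearest voxel of
    the other phase; the sphere covers every voxel whose center is closer
    than r + 0.5 to c (half-voxel slack so spheres between grid points
    reach the phase boundary).  Each True voxel receives the diameter 2·r
    of the largest covering sphere.

    Radii are processed in descending order.  When the phase has more than
    ``max_levels`` distinct EDT values, radii are binned (each bin
    represented by its smallest member, so thickness is never
    overestimated and the error is bounded by the bin width); with fewer
    distinct values the computation is exact and matches an exhaustive
    largest-covering-sphere search.
    """
    pore = np.asarray(pore, dtype=bool)
    if not pore.any():
        raise UndefinedResultError("no voxels in the phase: "
                                   "local thickness undefined")
    edt = ndimage.distance_transform_edt(pore)
    values = np.unique(edt[pore])
    if values.size > max_levels:
        edges = np.quantile(values, np.linspace(0, 1, max_levels + 1))
        # lower edge of each occupied bin, descending
        levels = np.unique(edges[np.searchsorted(edges, values,
                                                 side="right") - 1])[::-1]
    else:
        levels = values[::-1]
    thickness = np.zeros(pore.shape, dtype=np.float64)
    unassigned = pore.copy()
    for i, lev in enumerate(levels):
        if not unassigned.any():
            break
        hi = np.inf if i == 0 else levels[i - 1]
        centers = (edt >= lev) & (edt < hi) if np.isfinite(hi) \
            else (edt >= lev)
        if not centers.any():
            continue
        # distance from every voxel to the nearest center of this level
        dcen = ndimage.distance_transform_edt(~centers)
        covered = unassigned & (dcen < lev + 0.5)   # |v−c| < r + 0.5
        thickness[covered] = 2.0 * lev
        unassigned &= ~covered
    return thickness


def compute_pore_thickness(vol: VoxelVolume, n_bins: int = 20,
                           max_levels: int = 64,
                           ) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Volume-weighted mean pore diameter (μm) and its histogram.

    Every pore voxel contributes its local-thickness diameter; the
    histogram gives the pore-volume fraction per diameter bin (fractions
    sum to 1).  Raises :class:`UndefinedResultError` when the volume has
    no pore voxels — the quantity is undefined, not zero.
    """
    pore = vol.pore_mask()
    if not pore.any():
        raise UndefinedResultError("volume has no pore voxels: "
                                   "pore diameter undefined")
    th = local_thickness(pore, max_levels=max_levels) * vol.voxel_size_um
    vals = th[pore]
    mean = float(vals.mean())
    counts, edges = np.histogram(vals, bins=n_bins)
    fractions = counts / counts.sum()
    return mean, (edges, fractions)


def compute_morphometry(vol: VoxelVolume, with_thickness: bool = True,
                        smooth_sigma: float = 0.8,
                        max_levels: int = 64) -> MorphometryResult:
    """Full morphometry of one sample (Po, BS, TV, BS/TV, Po·Diam)."""
    spacing_mm = vol.voxel_size_um / 1000.0
    tv = vol.n_voxels * spacing_mm ** 3
    bs_tv = compute_surface_density(vol, smooth_sigma=smooth_sigma)
    if with_thickness and vol.n_pore > 0 and vol.n_material > 0:
        podiam, hist = compute_pore_thickness(vol, max_levels=max_levels)
    else:
        podiam, hist = float("nan"), (np.array([]), np.array([]))
    return MorphometryResult(Po=compute_porosity(vol),
                             BS=bs_tv * tv, TV=tv, BS_TV=bs_tv,
                             PoDiam_mean=podiam, thickness_histogram=hist)
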