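"""Phantoms and fixtures with known ground truth.

Every generator returns its output together with the analytically known
quantities (porosity, interface area, thickness, curve slope/area, fractal
dimension) so that each pipeline stage can be validated without any
external data:

* analytic solids (slab, sphere, cylinder) — closed-form morphometry;
* Gaussian-random-field "trabecular" volumes — porosity fixed exactly by
  quantile thresholding, structure scale set by the field correlation
  length, emulating high-/low-density cancellous bone cores;
* random sphere packings with carvable intra-granule porosity — emulating
  stacks of porous ceramic granules settled in a tube;
* Sierpinski carpet and fractional-Brownian-motion surfaces — fractal
  fixtures with known box-counting dimension;
* synthetic compression curves — a concave toe followed by a linear
  region of known slope, with optional Gaussian load noise.

All stochastic generators are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .biomech import LoadDisplacementCurve
from .volume import VoxelVolume


class PackingError(RuntimeError):
    """Random sequential addition failed to place the requested granules."""


# --------------------------------------------------------------------------
# analytic solids
# --------------------------------------------------------------------------

def make_solid(kind: str, shape: tuple[int, int, int], *,
               voxel_size_um: float = 10.0,
               thickness_vox: int | None = None,
               radius_vox: float | None = None,
               axis: int = 0,
               phase: str = "material") -> tuple[VoxelVolume, dict]:
    """Voxelize a slab, sphere or cylinder with closed-form ground truth.

    Voxelization is by center-of-voxel inclusion (no antialiasing), so
    voxel counts are exact integers.  ``phase`` selects whether the solid
    is the material or the pore phase.  Returns ``(volume, truth)`` where
    ``truth`` holds porosity fraction, interface area (voxel² and mm²) and,
    where defined, the solid's thickness/diameter in voxels.
    """
    nz, ny, nx = shape
    if kind == "slab":
        if thickness_vox is None:
            raise ValueError("slab needs thickness_vox")
        if thickness_vox > shape[axis]:
            raise ValueError("slab thicker than the box")
        inside = np.zeros(shape, dtype=bool)
        lo = (shape[axis] - thickness_vox) // 2
        sl = [slice(None)] * 3
        sl[axis] = slice(lo, lo + thickness_vox)
        inside[tuple(sl)] = True
        cross_section = inside.size // shape[axis]
        n_faces = 2 - (lo == 0) - (lo + thickness_vox == shape[axis])
        truth = {"solid_fraction": thickness_vox / shape[axis],
                 "interface_area_vox2": float(n_faces * cross_section),
                 "thickness_vox": float(thickness_vox)}
    elif kind == "sphere":
        if radius_vox is None:
            raise ValueError("sphere needs radius_vox")
        center = ((nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2)
        if radius_vox > min(center) + 0.5:
            raise ValueError("sphere does not fit inside the box")
        zz, yy, xx = np.ogrid[:nz, :ny, :nx]
        r2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
              + (xx - center[2]) ** 2)
        inside = r2 <= radius_vox ** 2
        truth = {"solid_fraction": (4.0 / 3.0) * np.pi * radius_vox ** 3
                 / inside.size,
                 "interface_area_vox2": 4.0 * np.pi * radius_vox ** 2,
                 "thickness_vox": 2.0 * radius_vox}
    elif kind == "cylinder":
        if radius_vox is None:
            raise ValueError("cylinder needs radius_vox")
        cy, cx = (ny - 1) / 2, (nx - 1) / 2
        if radius_vox > min(cy, cx) + 0.5:
            raise ValueError("cylinder does not fit inside the box")
        yy, xx = np.ogrid[:ny, :nx]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox ** 2
        inside = np.broadcast_to(disk, shape).copy()
        truth = {"solid_fraction": np.pi * radius_vox ** 2 / (ny * nx),
                 "interface_area_vox2": 2.0 * np.pi * radius_vox * nz,
                 "thickness_vox": 2.0 * radius_vox}
    else:
        raise ValueError(f"unknown solid kind {kind!r}")

    if phase == "material":
        mask = inside
        truth["porosity_fraction"] = 1.0 - truth["solid_fraction"]
    elif phase == "pore":
        mask = ~inside
        truth["porosity_fraction"] = truth["solid_fraction"]
    else:
        raise ValueError("phase must be 'material' or 'pore'")
    truth["interface_area_mm2"] = (truth["interface_area_vox2"]
                                   * (voxel_size_um / 1000.0) ** 2)
    vol = VoxelVolume(mask, voxel_size_um,
                      provenance=f"make_solid({kind}, phase={phase})")
    return vol, truth


# --------------------------------------------------------------------------
# Gaussian-random-field trabecular phantom
# --------------------------------------------------------------------------

def make_grf_trabecular(shape: tuple[int, int, int],
                        target_porosity: float,
                        correlation_length_um: float,
                        seed: int,
                        voxel_size_um: float = 10.0,
                        ) -> tuple[VoxelVolume, dict]:
    """Trabecular-bone-like binary volume from a smoothed Gaussian field.

    White noise is filtered with an isotropic Gaussian kernel of
    sd = correlation_length_um / voxel_size_um voxels, then thresholded at
    the ``target_porosity`` quantile of its own values, so the realized
    pore fraction equals the target to within one voxel by construction.
    Larger correlation length gives coarser trabeculae.
    """
    if not 0.0 < target_porosity < 1.0:
        raise ValueError("target_porosity must be in (0, 1)")
    rng = np.random.default_rng(seed)
    field = rng.standard_normal(shape)
    sigma = correlation_length_um / voxel_size_um
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="wrap")
    if field.std() == 0:
        raise RuntimeError("degenerate field: zero variance after filtering")
    # exact order-statistic threshold: exactly round(target*N) pore voxels
    n_pore = int(round(target_porosity * field.size))
    flat = field.ravel()
    if n_pore == 0:
        mask = np.ones(shape, dtype=bool)
    else:
        kth = np.partition(flat, n_pore - 1)[n_pore - 1]
        mask = field > kth               # material above the quantile
        # ties at the threshold could remove extra voxels; resolve exactly
        short = mask.size - n_pore - int(np.count_nonzero(mask))
        if short:
            tie_idx = np.flatnonzero(flat == kth)[:short]
            mask.ravel()[tie_idx] = True
    realized = 1.0 - np.count_nonzero(mask) / mask.size
    truth = {"porosity_fraction": realized,
             "target_porosity": target_porosity,
             "correlation_length_um": correlation_length_um}
    vol = VoxelVolume(mask, voxel_size_um,
                      provenance=f"grf_trabecular(target={target_porosity}, "
                                 f"corr={correlation_length_um}um, seed={seed})")
    return vol, truth


# --------------------------------------------------------------------------
# granule packing phantom
# --------------------------------------------------------------------------

def make_granule_packing(shape: tuple[int, int, int],
                         n_granules: int,
                         granule_diameter_um: float,
                         inner_porosity: float,
                         seed: int,
                         voxel_size_um: float = 10.0,
                         max_attempts_per_granule: int = 2000,
                         allow_boundary_clip: bool = True,
                         ) -> tuple[VoxelVolume, dict]:
    """Stack of porous spherical granules by random sequential addition.

    Non-overlapping spheres of the given diameter are placed uniformly at
    random (rejecting overlaps); each granule is then carved with small
    internal cavities (spheres of ~1/5 the granule diameter) until its
    material fraction is (1 - inner_porosity) ± 2%, emulating the
    foam-replica voids of sintered ceramic granules.  Spheres may be
    clipped by the container wall (granules settle against the tube), or
    required to fit entirely inside with ``allow_boundary_clip=False``.

    Raises :class:`PackingError`, reporting the achieved count, if the
    retry budget is exhausted before all granules are placed.
    """
    if n_granules < 1:
        raise ValueError("n_granules must be >= 1")
    if not 0.0 <= inner_porosity < 1.0:
        raise ValueError("inner_porosity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    r = granule_diameter_um / voxel_size_um / 2.0
    nz, ny, nx = shape
    lo = 0.0 if allow_boundary_clip else r
    his = [n - 1 - (0.0 if allow_boundary_clip else r) for n in shape]
    if any(h < lo for h in his):
        raise ValueError("granule larger than the box")
    centers: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_granule * n_granules
    while len(centers) < n_granules:
        if attempts >= budget:
            raise PackingError(
                f"placed only {len(centers)} of {n_granules} granules after "
                f"{budget} attempts (diameter {granule_diameter_um} um in "
                f"box {shape})")
        attempts += 1
        c = np.array([rng.uniform(lo, hi) for hi in his])
        if all(np.sum((c - p) ** 2) >= (2 * r) ** 2 for p in centers):
            centers.append(c)

    mask = np.zeros(shape, dtype=bool)
    rc = max(1.5, r / 5.0)
    for c in centers:
        # work in the granule's bounding box only
        lo_idx = [max(0, int(np.floor(ci - r - 1))) for ci in c]
        hi_idx = [min(n, int(np.ceil(ci + r + 2)))
                  for ci, n in zip(c, shape)]
        sl = tuple(slice(a, b) for a, b in zip(lo_idx, hi_idx))
        zz, yy, xx = np.meshgrid(*[np.arange(a, b)
                                   for a, b in zip(lo_idx, hi_idx)],
                                 indexing="ij", sparse=True)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        grain = d2 <= r ** 2
        if inner_porosity > 0:
            n_solid = int(np.count_nonzero(grain))
            target = (1.0 - inner_porosity) * n_solid
            for _ in range(4000):
                n_now = int(np.count_nonzero(grain))
                if n_now <= target or abs(n_now - target) <= 0.02 * n_solid:
                    break
                cav = c + rng.uniform(-r, r, size=3)
                if np.sum((cav - c) ** 2) > r ** 2:
                    continue
                d2c = ((zz - cav[0]) ** 2 + (yy - cav[1]) ** 2
                       + (xx - cav[2]) ** 2)
                grain &= ~(d2c <= rc ** 2)
        mask[sl] |= grain

    porosity = 1.0 - np.count_nonzero(mask) / mask.size
    truth = {"porosity_fraction": porosity,
             "n_granules": n_granules,
             "granule_radius_vox": r,
             "inner_porosity": inner_porosity}
    vol = VoxelVolume(mask, voxel_size_um,
                      provenance=f"granule_packing(n={n_granules}, "
                                 f"d={granule_diameter_um}um, "
                                 f"inner_po={inner_porosity}, seed={seed})")
    return vol, truth


# --------------------------------------------------------------------------
# fractal fixtures
# --------------------------------------------------------------------------

def make_sierpinski2d(level: int) -> np.ndarray:
    """Sierpinski carpet of side 3**level as a boolean image.

    Filled-pixel count is 8**level; theoretical box-counting dimension
    log 8 / log 3 ≈ 1.8928.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    cell = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    img = cell
    for _ in range(level - 1):
        img = np.kron(img, cell)
    return img


def make_fbm_surface(shape2d: tuple[int, int], hurst: float,
                     seed: int) -> np.ndarray:
    """Fractional-Brownian-motion surface by spectral synthesis.

    The Fourier amplitudes of white noise are scaled by f^-(hurst+1), the
    2D fBm spectrum; the theoretical box-counting (surface) dimension of
    the resulting intensity landscape is 3 - hurst.  Output is float
    rescaled to [0, 255].
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ny, nx = shape2d
    noise = rng.standard_normal(shape2d)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf                       # kill the DC mode
    amp = f ** (-(hurst + 1.0))
    surf = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    surf -= surf.min()
    if surf.max() > 0:
        surf *= 255.0 / surf.max()
    return surf


# --------------------------------------------------------------------------
# compression curves
# --------------------------------------------------------------------------

def make_compression_curve(stiffness_true: float,
                           toe_length_mm: float = 0.0,
                           load_cap: float = 400.0,
                           noise_sd: float = 0.0,
                           seed: int = 0,
                           step_mm: float = 0.001,
                           ) -> tuple[LoadDisplacementCurve, dict]:
    """Synthetic compression trace: concave toe, then a linear region.

    The noiseless load is quadratic over the toe (slope rising from 0 to
    the true stiffness, C1-continuous) and linear thereafter, truncated
    just past the load cap.  Gaussian noise of sd ``noise_sd`` N is added
    to the load.  ``step_mm`` is the displacement sampling interval
    (default 1 um: a testing machine sampling at ~10 Hz while moving at
    ~0.5 mm/min records about one point per micron).

    Returns the curve and the analytic ground truth: the true slope, the
    displacement at the cap crossing, and the exact area under the
    noiseless curve up to the crossing.
    """
    if stiffness_true <= 0:
        raise ValueError("stiffness_true must be > 0")
    if load_cap <= 0:
        raise ValueError("load_cap must be > 0")
    k, toe = stiffness_true, toe_length_mm
    load_at_toe = k * toe / 2.0
    if load_at_toe >= load_cap:
        raise ValueError("toe region alone exceeds the load cap")
    d_cap = toe / 2.0 + load_cap / k
    d = np.arange(0.0, d_cap + 20 * step_mm, step_mm)

    def noiseless(x):
        x = np.asarray(x, dtype=float)
        out = np.where(x < toe,
                       k * x ** 2 / (2.0 * toe) if toe > 0 else k * x,
                       k * (x - toe / 2.0))
        return out

    f = noiseless(d)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=f.size)
    # analytic area: toe integral k*toe^2/6, then linear ramp to the cap
    area_toe = k * toe ** 2 / 6.0
    area_lin = (load_at_toe + load_cap) / 2.0 * (d_cap - toe)
    truth = {"stiffness": k,
             "max_displacement": d_cap,
             "work_to_failure": area_toe + area_lin}
    return LoadDisplacementCurve(d, f, load_cap=load_cap), truth
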