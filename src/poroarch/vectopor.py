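"""Frontal-plane vector projection of porosity.

The binarized stack is collapsed to a 2D "frontal plane" built line by
line: for each tomographic slice (one output row) and each in-slice
column, the pore voxels along the projection axis are counted and the
pore fraction stored.  The map is rendered with a pseudo-color look-up
table running from deep blue (no porosity) to red (fully porous), and a
grayscale version (intensity = 255 × fraction) is the input to the
fractal analysis.

Pore counts are kept as integers alongside the depth, so the map
conserves porosity exactly: total pore count over the map equals the
volumetric pore-voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume

#: Default LUT anchors: deep blue -> cyan -> yellow -> red.
DEFAULT_LUT_ANCHORS: tuple[tuple[float, tuple[int, int, int]], ...] = (
    (0.0, (0, 0, 128)),
    (1.0 / 3.0, (0, 255, 255)),
    (2.0 / 3.0, (255, 255, 0)),
    (1.0, (255, 0, 0)),
)


@dataclass
class LUTSpec:
    """Piecewise-linear color table over the pore fraction [0, 1]."""

    anchors: tuple = DEFAULT_LUT_ANCHORS
    n_entries: int = 256

    def __post_init__(self) -> None:
        fr = [a[0] for a in self.anchors]
        if fr[0] != 0.0 or fr[-1] != 1.0 or any(
                b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("anchors must be strictly increasing in "
                             "fraction, starting at 0 and ending at 1")

    def table(self) -> np.ndarray:
        """The (n_entries, 3) uint8 color table."""
        fr = np.array([a[0] for a in self.anchors])
        cols = np.array([a[1] for a in self.anchors], dtype=float)
        x = np.linspace(0.0, 1.0, self.n_entries)
        rgb = np.stack([np.interp(x, fr, cols[:, c]) for c in range(3)],
                       axis=1)
        return np.rint(rgb).astype(np.uint8)


@dataclass
class FrontalPlaneMap:
    """Per-column pore fractions: rows = slices (z), columns = x."""

    pore_counts: np.ndarray     # integer pore-voxel counts per (z, x) column
    depth: int                  # voxels per projection vector
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.pore_counts = np.asarray(self.pore_counts)
        if self.pore_counts.ndim != 2:
            raise ValueError("pore_counts must be 2D (z, x)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    @property
    def fractions(self) -> np.ndarray:
        return self.pore_counts / self.depth

    def mean_fraction(self) -> float:
        """Mean pore fraction of the map, computed from integer counts so
        it equals the volumetric porosity fraction exactly."""
        return int(self.pore_counts.sum()) / (self.pore_counts.size
                                              * self.depth)


def project_frontal(vol: VoxelVolume, axis: str = "y") -> FrontalPlaneMap:
    """Collapse a binarized volume to its frontal-plane porosity map.

    Each slice contributes one row; within a slice the pore voxels are
    counted along the chosen in-slice axis (default ``y``, the row axis,
    giving a z × x image).
    """
    pore = vol.pore_mask()
    if axis == "y":
        counts = pore.sum(axis=1)
        depth = vol.shape[1]
    elif axis == "x":
        counts = pore.sum(axis=2)
        depth = vol.shape[2]
    else:
        raise ValueError("projection axis must be 'y' or 'x' (in-slice)")
    return FrontalPlaneMap(counts.astype(np.int64), depth, vol.voxel_size_um)


def frontal_grayscale(fmap: FrontalPlaneMap) -> np.ndarray:
    """8-bit grayscale frontal image: round(255 × fraction), half away
    from zero (0.5 → 128).  This is the image the fractal module analyzes."""
    scaled = 255.0 * fmap.fractions
    return np.floor(scaled + 0.5).astype(np.uint8)


def apply_lut(fmap: FrontalPlaneMap, lut: LUTSpec | None = None) -> np.ndarray:
    """Render the map as an RGB image through the LUT.

    Fractions are quantized to the table length, so rendering is
    bit-exact for a given :class:`LUTSpec`.
    """
    lut = lut or LUTSpec()
    table = lut.table()
    idx = np.floor(fmap.fractions * (lut.n_entries - 1) + 0.5).astype(int)
    return table[np.clip(idx, 0, lut.n_entries - 1)]


def interpolate_color(fraction: float, lut: LUTSpec | None = None
                      ) -> tuple[int, int, int]:
    """Color of one pore fraction under the LUT's piecewise-linear ramp."""
    lut = lut or LUTSpec()
    fr = np.array([a[0] for a in lut.anchors])
    cols = np.array([a[1] for a in lut.anchors], dtype=float)
    rgb = [float(np.interp(fraction, fr, cols[:, c])) for c in range(3)]
    # half-up rounding with an epsilon so exact .5 midpoints computed
    # through float anchor fractions (1/3, 2/3) round upward
    return tuple(int(np.floor(v + 0.5 + 1e-9)) for v in rgb)


def save_frontal_images(fmap: FrontalPlaneMap, out_prefix,
                        lut: LUTSpec | None = None) -> dict:
    """Write the 16-bit grayscale PNG, the RGB LUT PNG and the fraction CSV."""
    from pathlib import Path

    import imageio.v3 as iio
    import pandas as pd

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    gray16 = np.round(fmap.fractions * 65535).astype(np.uint16)
    paths = {"gray16": out_prefix.with_suffix(".gray16.png"),
             "rgb": out_prefix.with_suffix(".lut.png"),
             "csv": out_prefix.with_suffix(".fractions.csv")}
    iio.imwrite(paths["gray16"], gray16)
    iio.imwrite(paths["rgb"], apply_lut(fmap, lut))
    pd.DataFrame(fmap.fractions).to_csv(paths["csv"], index=False,
                                        header=False)
    return paths
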