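"""Study orchestration: phantoms/stacks -> morphometry -> frontal plane ->
fractal parameters -> group statistics, with a resolved-config record.

A run is described by a :class:`RunConfig` (serializable to/from YAML).
Each sample is either a slice-stack directory on disk or an inline
phantom specification; per-sample randomness is drawn from a stream
seeded by ``global_seed + sample index``, so adding samples never shifts
the phantoms of existing ones.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fractal, morphometry, stack_io, stats_compare, synthetic_data
from . import vectopor as vp
from .volume import RoiSpec, VoxelVolume

log = logging.getLogger("poroarch")


@dataclass
class SampleSpec:
    """One study sample: a stack directory or an inline phantom."""

    sample_id: str
    group: str
    stack_dir: str | None = None        # directory of slice images, or
    phantom: dict | None = None         # synthetic_data spec {kind, ...}
    threshold: float | None = None      # overrides the study threshold


@dataclass
class RunConfig:
    samples: list[SampleSpec]
    voxel_size_um: float = 4.95
    threshold: float = 128.0
    roi: dict | None = None             # {side_mm, height_mm, origin}
    projection_axis: str = "y"
    fractal_sizes: list[int] | None = None
    biomech_cap: float = 400.0
    out_dir: str = "poroarch_out"
    global_seed: int = 0
    with_thickness: bool = True
    thickness_max_levels: int = 128

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["samples"] = [SampleSpec(**s) for s in raw.get("samples", [])]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _resolve_sample(cfg: RunConfig, spec: SampleSpec,
                    index: int) -> VoxelVolume:
    if (spec.stack_dir is None) == (spec.phantom is None):
        raise ValueError(f"sample {spec.sample_id!r} must define exactly one "
                         "of stack_dir or phantom")
    if spec.stack_dir is not None:
        gray = stack_io.read_slice_stack(spec.stack_dir,
                                         voxel_size_um=cfg.voxel_size_um)
        thr = spec.threshold if spec.threshold is not None else cfg.threshold
        vol = stack_io.global_threshold(gray, thr)
    else:
        ph = dict(spec.phantom)
        kind = ph.pop("kind")
        ph.setdefault("voxel_size_um", cfg.voxel_size_um)
        seed = int(ph.pop("seed", cfg.global_seed + index))
        if kind == "grf_trabecular":
            vol, _ = synthetic_data.make_grf_trabecular(
                shape=tuple(ph.pop("shape")), seed=seed, **ph)
        elif kind == "granule_packing":
            vol, _ = synthetic_data.make_granule_packing(
                shape=tuple(ph.pop("shape")), seed=seed, **ph)
        elif kind in ("slab", "sphere", "cylinder"):
            vol, _ = synthetic_data.make_solid(
                kind, shape=tuple(ph.pop("shape")), **ph)
        else:
            raise ValueError(f"unknown phantom kind {kind!r}")
    if cfg.roi:
        roi = RoiSpec(side_mm=cfg.roi["side_mm"],
                      height_mm=cfg.roi["height_mm"],
                      origin=tuple(cfg.roi.get("origin", (0, 0, 0))))
        vol = stack_io.extract_roi(vol, roi)
    return vol


def run_sample(cfg: RunConfig, spec: SampleSpec, index: int = 0,
               write_outputs: bool = True) -> dict:
    """Run the full per-sample pipeline; returns the result bundle."""
    t0 = time.time()
    vol = _resolve_sample(cfg, spec, index)
    morpho = morphometry.compute_morphometry(
        vol, with_thickness=cfg.with_thickness,
        max_levels=cfg.thickness_max_levels)
    fmap = vp.project_frontal(vol, axis=cfg.projection_axis)
    gray = vp.frontal_grayscale(fmap)
    sizes = (np.asarray(cfg.fractal_sizes, dtype=int)
             if cfg.fractal_sizes else None)
    fres = fractal.differential_boxcount_dimension(gray, sizes=sizes)
    lres = fractal.gliding_box_lacunarity(gray, sizes=sizes)
    bundle = {"sample_id": spec.sample_id, "group": spec.group,
              "morphometry": morpho, "frontal_map": fmap,
              "fractal": fres, "lacunarity": lres,
              "wall_time_s": time.time() - t0}
    if write_outputs:
        out = Path(cfg.out_dir) / spec.sample_id
        out.mkdir(parents=True, exist_ok=True)
        row = {"sample_id": spec.sample_id, "group": spec.group,
               **morpho.to_dict(), "Df": fres.Df, "Df_r2": fres.r2,
               "lacunarity": lres.lam}
        pd.DataFrame([row]).to_csv(out / "morphometry.csv", index=False)
        with open(out / "morphometry.json", "w") as fh:
            json.dump(row, fh, indent=2)
        vp.save_frontal_images(fmap, out / "frontal")
    log.info("sample %s done in %.1f s", spec.sample_id,
             bundle["wall_time_s"])
    return bundle


#: parameters collected into the study-level comparison table
STUDY_PARAMETERS = ("Po", "BS_TV", "PoDiam_mean", "Df", "lacunarity")


def reference_study_config(seed: int = 0, n_per_group: int = 3,
                           shape: tuple[int, int, int] = (128, 128, 128),
                           out_dir: str = "poroarch_out",
                           with_thickness: bool = True) -> RunConfig:
    """The package's reference four-group phantom study (scaled down).

    Two trabecular-bone-like Gaussian-random-field groups — high density
    (HD-like, porosity 0.691) and low density (LD-like, 0.888) — and two
    granule-stack groups of identical sphere packings differing only in
    intra-granule porosity: LP-like solid granules (twice the material
    mass) versus HP-like granules carved to 50% inner porosity.  Voxels
    are 10 μm; granules are 240 μm (about 0.19 of the box side, the
    granule-to-tube ratio of a millimeter-scale granule in a centimeter
    tube); the GRF correlation length is 120 μm.
    """
    samples = []
    groups = {
        "HD": {"kind": "grf_trabecular", "shape": list(shape),
               "target_porosity": 0.691, "correlation_length_um": 120.0},
        "LD": {"kind": "grf_trabecular", "shape": list(shape),
               "target_porosity": 0.888, "correlation_length_um": 120.0},
        "LP": {"kind": "granule_packing", "shape": list(shape),
               "n_granules": 130, "granule_diameter_um": 240.0,
               "inner_porosity": 0.0},
        "HP": {"kind": "granule_packing", "shape": list(shape),
               "n_granules": 130, "granule_diameter_um": 240.0,
               "inner_porosity": 0.5},
    }
    for gi, (grp, phantom) in enumerate(groups.items()):
        for i in range(n_per_group):
            ph = dict(phantom)
            ph["seed"] = seed + 100 * (gi + 1) + i
            samples.append(SampleSpec(sample_id=f"{grp}_{i}", group=grp,
                                      phantom=ph))
    return RunConfig(samples=samples, voxel_size_um=10.0,
                     out_dir=out_dir, global_seed=seed,
                     with_thickness=with_thickness,
                     thickness_max_levels=32)


def run_study(cfg: RunConfig, write_outputs: bool = True
              ) -> tuple[stats_compare.ComparisonReport, pd.DataFrame]:
    """Run every sample and build the study-level comparison table.

    Per-sample failures halt that sample only; the report is built from
    the completed samples with their realized n.
    """
    if not cfg.samples:
        raise ValueError("empty sample list")
    groups = {s.group for s in cfg.samples}
    records = []
    failures = []
    for idx, spec in enumerate(cfg.samples):
        try:
            bundle = run_sample(cfg, spec, index=idx,
                                write_outputs=write_outputs)
        except Exception as exc:           # continue with other samples
            failures.append((spec.sample_id, repr(exc)))
            log.error("sample %s failed: %s", spec.sample_id, exc)
            continue
        m = bundle["morphometry"]
        vals = {"Po": m.Po, "BS_TV": m.BS_TV, "PoDiam_mean": m.PoDiam_mean,
                "Df": bundle["fractal"].Df,
                "lacunarity": bundle["lacunarity"].lam}
        for param in STUDY_PARAMETERS:
            records.append({"sample_id": spec.sample_id,
                            "group": spec.group, "parameter": param,
                            "value": vals[param]})
    if not records:
        raise RuntimeError(f"all samples failed: {failures}")
    long_df = pd.DataFrame(records)
    if len(groups) < 2:
        log.warning("single group configured: no statistical tests")
        report = stats_compare.ComparisonReport(
            table=long_df.groupby("parameter", sort=False)["value"]
            .agg(["mean", "std", "count"]).reset_index(),
            omnibus={}, pairwise={},
            warnings=["single group: no tests"] +
                     [f"{sid} failed: {err}" for sid, err in failures])
    else:
        report = stats_compare.build_table(long_df)
        report.warnings += [f"{sid} failed: {err}" for sid, err in failures]
    if write_outputs:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        long_df.to_csv(out / "study_long.csv", index=False)
        report.table.to_csv(out / "study_table.csv", index=False)
        with open(out / "study_table.md", "w") as fh:
            if report.omnibus:
                fh.write(stats_compare.report_markdown(report))
        cfg.to_yaml(out / "resolved_config.yaml")
    return report, long_df
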