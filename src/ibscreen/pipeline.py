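"""End-to-end orchestration: simulate/ingest -> preprocess -> segment ->
classify -> [associate], with strict YAML configuration and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import build_organelle_mask, score_field, summarize_association
from .classify import build_cell_records, summarize_population
from .field import CHANNEL_AGGREGATE, CHANNEL_ORGANELLE, ImageField
from .io import read_image, sha256_of, write_image, write_manifest, write_table
from .preprocess import preprocess_field
from .segment import assign_inclusions, segment_cells, segment_inclusions
from .simulate import generate_field, get_preset

logger = logging.getLogger("ibscreen")

__all__ = [
    "PipelineConfig",
    "FieldQuantification",
    "quantify_field",
    "run_pipeline",
]


@dataclass(frozen=True)
class SegmentationParams:
    min_cell_area_px: int = 200
    max_cell_area_px: int = 5000
    min_ib_area_px: int = 4
    intensity_k: float = 6.0
    marker_h: float = 2.0


@dataclass(frozen=True)
class PreprocessParams:
    smoothing_scale_px: float = 64.0
    subtract_radius_px: int = 6


@dataclass(frozen=True)
class AssociationParams:
    enabled: bool = False
    probe_distance_px: float = 3.0
    surrounded_threshold: float = 0.5


@dataclass(frozen=True)
class SimulateParams:
    preset: str = "stationary"
    n_fields: int = 2
    n_cells: int = 150
    shell_probability: float = 0.0
    write_images: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable; unknown keys rejected)."""

    out_dir: str = "run"
    seed: int = 0
    input_images: tuple[str, ...] = ()
    simulate: SimulateParams = dc_field(default_factory=SimulateParams)
    preprocess: PreprocessParams = dc_field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    association: AssociationParams = dc_field(default_factory=AssociationParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            allowed = set(klass.__dataclass_fields__)
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(
                    f"unknown config key(s) for {klass.__name__}: {sorted(unknown)}")
            return klass(**sub)

        d = dict(d)
        nested = {"simulate": SimulateParams, "preprocess": PreprocessParams,
                  "segmentation": SegmentationParams,
                  "association": AssociationParams}
        kwargs = {}
        for key, klass in nested.items():
            if key in d:
                kwargs[key] = build(klass, d.pop(key) or {})
        if "input_images" in d:
            kwargs["input_images"] = tuple(d.pop("input_images") or ())
        unknown = set(d) - {"out_dir", "seed"}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class FieldQuantification:
    """Everything the pipeline measures on one field."""

    field_id: str
    cell_records: pd.DataFrame
    ib_records: pd.DataFrame
    cell_mask: "np.ndarray"
    ib_mask: "np.ndarray"
    association: pd.DataFrame | None = None


def quantify_field(field: ImageField,
                   preprocess_params: PreprocessParams = PreprocessParams(),
                   seg_params: SegmentationParams = SegmentationParams(),
                   assoc_params: AssociationParams | None = None,
                   ) -> FieldQuantification:
    """Run preprocessing, segmentation, mask combination and classification on
    one field; optionally score organelle encirclement when the field has an
    organelle channel."""
    pre = preprocess_field(field,
                           smoothing_scale_px=preprocess_params.smoothing_scale_px,
                           subtract_radius_px=preprocess_params.subtract_radius_px)
    cell_mask = segment_cells(pre.corrected[CHANNEL_AGGREGATE],
                              min_area_px=seg_params.min_cell_area_px,
                              max_area_px=seg_params.max_cell_area_px,
                              marker_h=seg_params.marker_h)
    ib_mask = segment_inclusions(pre.residual[CHANNEL_AGGREGATE], cell_mask,
                                 min_area_px=seg_params.min_ib_area_px,
                                 intensity_k=seg_params.intensity_k)
    ib_records, cell_counts = assign_inclusions(
        cell_mask, ib_mask, intensity=pre.corrected[CHANNEL_AGGREGATE],
        field_id=field.field_id)
    cell_records = build_cell_records(cell_counts, cell_mask)

    association = None
    if (assoc_params is not None and assoc_params.enabled
            and CHANNEL_ORGANELLE in field.channels):
        organelle = build_organelle_mask(pre.residual[CHANNEL_ORGANELLE])
        association = score_field(
            ib_mask, ib_records, cell_records, organelle,
            probe_distance_px=assoc_params.probe_distance_px,
            threshold=assoc_params.surrounded_threshold,
            field_id=field.field_id)
    logger.info("field %s: %d cells, %d inclusions", field.field_id,
                cell_mask.n_objects, ib_mask.n_objects)
    return FieldQuantification(field.field_id, cell_records, ib_records,
                               cell_mask.labels, ib_mask.labels, association)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write result tables plus a manifest.

    Stages: simulate (or ingest input images) -> preprocess -> segment ->
    classify -> associate (optional).  Any stage error aborts with the stage
    name and field id.  Returns the manifest dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    fields: list[ImageField] = []
    stage = "ingest"
    try:
        if config.input_images:
            for p in config.input_images:
                fields.append(read_image(p))
        else:
            stage = "simulate"
            preset = get_preset(config.simulate.preset)
            ss = np.random.SeedSequence(config.seed)
            seeds = [int(c.generate_state(1)[0] % (2**31))
                     for c in ss.spawn(config.simulate.n_fields)]
            for j, s in enumerate(seeds):
                spec = preset.field_spec(
                    seed=s, n_cells=config.simulate.n_cells,
                    shell_probability=config.simulate.shell_probability)
                fld, gt = generate_field(spec, field_id=f"field_{j}")
                fields.append(fld)
                if config.simulate.write_images:
                    write_image(fld, out_dir / f"{fld.field_id}.tif")
                write_table(gt.cells, out_dir / f"{fld.field_id}_truth_cells.csv")
                write_table(gt.inclusions,
                            out_dir / f"{fld.field_id}_truth_inclusions.csv")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    all_cells, all_ibs, all_assoc = [], [], []
    assoc = config.association if config.association.enabled else None
    for fld in fields:
        stage = "quantify"
        try:
            q = quantify_field(fld, config.preprocess, config.segmentation, assoc)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on field {fld.field_id}: {exc}") from exc
        all_cells.append(q.cell_records)
        all_ibs.append(q.ib_records)
        if q.association is not None:
            all_assoc.append(q.association)

    cells = pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    ibs = pd.concat(all_ibs, ignore_index=True) if all_ibs else pd.DataFrame()
    outputs = {
        "cells.csv": write_table(cells, out_dir / "cells.csv"),
        "inclusions.csv": write_table(ibs, out_dir / "inclusions.csv"),
    }
    summary: dict = {"n_fields": len(fields)}
    if len(cells) and (~cells.border_flag).sum() > 0:
        summary["population"] = summarize_population(cells).as_dict()
    if all_assoc:
        assoc_df = pd.concat(all_assoc, ignore_index=True)
        outputs["association.csv"] = write_table(assoc_df,
                                                 out_dir / "association.csv")
        summary["association"] = summarize_association(assoc_df)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    outputs["summary.json"] = out_dir / "summary.json"

    manifest = {
        "software": {"name": "ibscreen", "version": __version__},
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "outputs": {name: sha256_of(p) for name, p in outputs.items()},
        "wall_time_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest
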