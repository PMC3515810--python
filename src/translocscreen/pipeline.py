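"""End-to-end orchestration: simulate -> segment -> quantify -> screen.

A single :class:`RunConfig` (YAML-serializable) drives every stage;
outputs are written with SHA-256 checksums into a manifest so a run is
fully reproducible from its config + master seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .errors import ValidationError
from .models import (AcquisitionSpec, CellModel, NoiseModel, QCPolicy,
                     SegmentationParams, TranslocationModel, asdict_flat)
from .quantify import filter_cells, measure_cells
from .screen import (anova_gate, aggregate_wells, dunnett_test,
                     heatmap_matrix, normalize_plate, render_heatmap)
from .segment import segment_cytoplasm, segment_nuclei
from .simulate import make_plate_layout, simulate_plate

log = logging.getLogger("translocscreen")


@dataclass
class RunConfig:
    """Complete, serializable description of one screening run."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    cells: CellModel = field(default_factory=CellModel)
    translocation: TranslocationModel = field(default_factory=TranslocationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCPolicy = field(default_factory=QCPolicy)
    rows: int = 8
    cols: int = 12
    n_samples: int = 12
    n_replicates: int = 4
    n_cells_per_field: int = 50
    active_samples: dict[str, float] = field(default_factory=dict)  # label -> dose
    sample_dose: float = 0.0  # dose applied to inactive samples
    alpha: float = 0.05
    two_sided: bool = True
    min_cells_per_well: int = 10
    seed: int = 0
    write_images: bool = True

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("rows", "cols", "n_samples", "n_replicates",
              "n_cells_per_field", "active_samples", "sample_dose", "alpha",
              "two_sided", "min_cells_per_well", "seed", "write_images")}
        for k in ("acquisition", "cells", "translocation", "noise",
                  "segmentation", "qc"):
            d[k] = asdict_flat(getattr(self, k))
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, key):
            sub = d.get(key, {})
            sub = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in sub.items()}
            return klass(**sub)
        kwargs = {k: v for k, v in d.items()
                  if k not in ("acquisition", "cells", "translocation",
                               "noise", "segmentation", "qc")}
        return cls(acquisition=build(AcquisitionSpec, "acquisition"),
                   cells=build(CellModel, "cells"),
                   translocation=build(TranslocationModel, "translocation"),
                   noise=build(NoiseModel, "noise"),
                   segmentation=build(SegmentationParams, "segmentation"),
                   qc=build(QCPolicy, "qc"), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ScreenResult:
    layout: pd.DataFrame
    cells: pd.DataFrame
    wells: pd.DataFrame
    hits: pd.DataFrame
    qc_tally: dict
    out_dir: Path | None = None


def _build_layout(cfg: RunConfig):
    layout = make_plate_layout(cfg.rows, cfg.cols, cfg.n_samples,
                               cfg.n_replicates, cfg.seed,
                               sample_dose=cfg.sample_dose,
                               positive_dose=100.0)
    if cfg.active_samples:
        from .simulate import WellSpec
        unknown = set(cfg.active_samples) - {w.treatment_label
                                             for w in layout.wells}
        if unknown:
            raise ValidationError(f"active_samples not in layout: {unknown}")
        wells = tuple(
            WellSpec(w.well_id, w.row, w.col, w.treatment_label,
                     w.treatment_class,
                     cfg.active_samples.get(w.treatment_label, w.dose),
                     w.replicate_group)
            for w in layout.wells)
        layout = type(layout)(layout.rows, layout.cols, wells)
    return layout


def run_screen_pipeline(config: RunConfig,
                        out_dir: str | Path | None = None) -> ScreenResult:
    """Simulate a plate, segment and measure every field, and call hits.

    When ``out_dir`` is given, all artifacts (images, label maps,
    per-cell CSV, well-summary CSV, hit table, heat-maps, config,
    manifest) are written there.
    """
    layout = _build_layout(config)
    log.info("plate layout: %d wells (%d samples x %d replicates)",
             len(layout.wells), config.n_samples, config.n_replicates)
    fields = simulate_plate(layout, config.acquisition, config.cells,
                            config.translocation, config.noise, config.seed,
                            n_cells=config.n_cells_per_field)
    written: list[str] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "images").mkdir(exist_ok=True)
        (out / "labels").mkdir(exist_ok=True)

    all_cells = []
    for well_id, fid, img, _gt in fields:
        nuc = segment_nuclei(img.dna, config.segmentation)
        pair = segment_cytoplasm(img.gfp, nuc, config.segmentation)
        recs = measure_cells(img, pair, config.qc)
        all_cells.append(recs)
        log.info("well %s field %d: %d cells measured", well_id, fid,
                 len(recs))
        if out is not None and config.write_images:
            name = tio.field_filename(well_id, fid)
            tio.write_field_tiff(out / "images" / name, img)
            tio.write_labels_tiff(out / "labels" / f"nuc_{name}", nuc)
            tio.write_labels_tiff(out / "labels" / f"cell_{name}",
                                  pair.cell_label_map)
            written += [f"images/{name}", f"labels/nuc_{name}",
                        f"labels/cell_{name}"]

    cells = pd.concat(all_cells, ignore_index=True)
    kept, tally = filter_cells(cells)
    wells = aggregate_wells(kept, layout,
                            min_cells_per_well=config.min_cells_per_well)
    wells = normalize_plate(wells)
    gate = anova_gate(wells)
    log.info("ANOVA gate: F=%.3g p=%.3g -> %s", gate.f_stat, gate.p_value,
             "passed" if gate.passed else "not passed")
    hits = dunnett_test(wells, alpha=config.alpha,
                        two_sided=config.two_sided, gate=gate)

    if out is not None:
        tio.write_layout_csv(out / "layout.csv", layout)
        cells.to_csv(out / "cells.csv", index=False)
        wells.to_csv(out / "wells.csv", index=False)
        hits.to_csv(out / "hits.csv", index=False)
        mat = heatmap_matrix(wells, value="normalized")
        mat.to_csv(out / "heatmap.csv")
        render_heatmap(mat, out / "heatmap.png",
                       title="Normalized N/C translocation")
        config.to_yaml(out / "config.yaml")
        written += ["layout.csv", "cells.csv", "wells.csv", "hits.csv",
                    "heatmap.csv", "heatmap.png", "config.yaml"]
        tio.write_manifest(out / "manifest.json", out, written,
                           config.to_dict(), config.seed)
    return ScreenResult(layout=tio.layout_to_frame(layout)
                        if not isinstance(layout, pd.DataFrame) else layout,
                        cells=cells, wells=wells, hits=hits, qc_tally=tally,
                        out_dir=out)


def make_demo_dataset(out_dir, seed: int = 0) -> ScreenResult:
    """Small demo plate: 12 samples, 2 planted actives, quick to run.

    Used by the docs tutorial and tests; writes images, ground truth
    and all derived tables under ``out_dir``.
    """
    cfg = RunConfig(
        acquisition=AcquisitionSpec(field_width_px=256, field_height_px=256,
                                    fields_per_well=1),
        n_samples=12, n_replicates=4, n_cells_per_field=12,
        active_samples={"S03": 100.0, "S08": 100.0},
        seed=seed,
    )
    return run_screen_pipeline(cfg, out_dir)
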