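"""File formats: multi-channel TIFFs, label TIFFs, layout CSVs, manifests."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .models import AcquisitionSpec
from .simulate import FieldImage, PlateLayout, layout_from_frame, layout_to_frame

CHANNEL_ORDER = ("dna", "gfp")

LAYOUT_COLUMNS = ["well_id", "row", "col", "treatment_label",
                  "treatment_class", "dose", "replicate_group"]


def field_filename(well_id: str, field_id: int) -> str:
    return f"{well_id}_f{field_id}.tif"


def write_field_tiff(path, field: FieldImage) -> None:
    """2-page TIFF, fixed channel order (DNA, GFP), metadata in tags."""
    meta = {"axes": "CYX", "channels": list(CHANNEL_ORDER),
            "well_id": field.well_id, "field_id": field.field_id,
            "pixel_size_nm": field.acq.pixel_size_nm,
            "bit_depth": field.acq.bit_depth}
    stack = np.stack([field.dna, field.gfp])
    tifffile.imwrite(path, stack, metadata=meta)


def read_field_tiff(path, acq: AcquisitionSpec | None = None) -> FieldImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValidationError(f"{path}: expected a 2-channel TIFF stack")
    if acq is None:
        acq = AcquisitionSpec(
            field_width_px=stack.shape[2], field_height_px=stack.shape[1],
            pixel_size_nm=float(meta.get("pixel_size_nm", 300.0)),
            bit_depth=int(meta.get("bit_depth", 16)), fields_per_well=1)
    return FieldImage(dna=stack[0], gfp=stack[1],
                      well_id=str(meta.get("well_id", Path(path).stem)),
                      field_id=int(meta.get("field_id", 0)), acq=acq)


def write_labels_tiff(path, label_map: np.ndarray) -> None:
    tifffile.imwrite(path, label_map.astype(np.int32))


def read_labels_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_layout_csv(path, layout: PlateLayout) -> None:
    layout_to_frame(layout)[LAYOUT_COLUMNS].to_csv(path, index=False)


def read_layout_csv(path) -> PlateLayout:
    df = pd.read_csv(path)
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"layout CSV missing columns: {sorted(missing)}")
    return layout_from_frame(df)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, out_dir, files: list[str], config: dict,
                   seed: int) -> None:
    """Machine-readable manifest linking every output to config + seed."""
    out_dir = Path(out_dir)
    entries = []
    for f in files:
        fp = out_dir / f
        if not fp.exists():
            raise ValidationError(f"manifest references missing file {f}")
        entries.append({"file": f, "sha256": sha256_file(fp),
                        "bytes": fp.stat().st_size})
    with open(path, "w") as fh:
        json.dump({"seed": seed, "config": config, "files": entries}, fh,
                  indent=2, default=str)
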