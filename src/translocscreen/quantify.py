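"""Per-cell compartment intensities and the N/C translocation ratio.

The assay's core readout: for every segmented cell, the mean
(background-corrected) GFP intensity over the nucleus and over the
cytoplasm, and their ratio.  Compartment means are taken on collared
regions (nucleus eroded, cytoplasm excluding a ring around the nucleus)
so that PSF blur at the nuclear boundary does not mix the two signals;
reported areas are the full segmented compartments.  Cells failing
quality control carry flags and are dropped before well aggregation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import ShapeError
from .models import QCPolicy
from .segment import LabelPair
from .simulate import FieldImage

__all__ = ["measure_cells", "filter_cells", "QC_FLAGS"]

QC_FLAGS = ("too_small", "border", "degenerate_cyto", "saturated", "low_signal")


def _labeled_means(values: np.ndarray, labels: np.ndarray,
                   ids: np.ndarray) -> np.ndarray:
    return np.asarray(ndi.mean(values, labels=labels, index=ids))


def measure_cells(field: FieldImage, labels: LabelPair,
                  policy: QCPolicy | None = None) -> pd.DataFrame:
    """One record per segmented cell.

    Columns: well_id, field_id, cell_id, nucleus_area_px,
    cytoplasm_area_px, mean_nuclear_intensity, mean_cytoplasmic_intensity,
    nc_ratio, background, plus one boolean column per QC flag and a
    ``qc_pass`` summary.  A cell whose cytoplasm mean is non-positive
    gets ``nc_ratio = NaN`` and a flag instead of a division error.
    """
    policy = policy or QCPolicy()
    gfp = np.asarray(field.gfp, dtype=float)
    nuc, cell = labels.nucleus_label_map, labels.cell_label_map
    if gfp.shape != cell.shape:
        raise ShapeError("field and label maps differ in shape")

    ids = labels.labels
    if ids.size == 0:
        return _empty_records(field)

    background = 0.0
    if policy.background_policy == "median":
        outside = cell == 0
        if outside.any():
            background = float(np.median(gfp[outside]))
    g = gfp - background

    cyto = np.where(nuc > 0, 0, cell)  # cytoplasm = cell minus nucleus
    nuc_area = np.asarray(ndi.sum_labels(np.ones_like(cell), nuc, ids))
    cyto_area = np.asarray(ndi.sum_labels(np.ones_like(cell), cyto, ids))

    # collared measurement regions, falling back to the full compartment
    # when erosion/the gap would leave nothing to measure
    nuc_meas, cyto_meas = nuc, cyto
    if (policy.nucleus_erosion_px > 0 or policy.boundary_gap_px > 0
            or policy.cell_edge_erosion_px > 0):
        nuc_mask = nuc > 0
        if policy.nucleus_erosion_px > 0:
            eroded = ndi.binary_erosion(
                nuc_mask, iterations=policy.nucleus_erosion_px)
            nuc_meas = np.where(eroded, nuc, 0)
        if policy.boundary_gap_px > 0:
            dist = ndi.distance_transform_edt(~nuc_mask)
            cyto_meas = np.where(dist > policy.boundary_gap_px, cyto, 0)
        if policy.cell_edge_erosion_px > 0:
            inner = ndi.binary_erosion(cell > 0,
                                       iterations=policy.cell_edge_erosion_px)
            cyto_meas = np.where(inner, cyto_meas, 0)
    nmeas_area = np.asarray(ndi.sum_labels(np.ones_like(cell), nuc_meas, ids))
    cmeas_area = np.asarray(ndi.sum_labels(np.ones_like(cell), cyto_meas, ids))

    with np.errstate(invalid="ignore"):
        mean_n = np.where(nmeas_area > 0, _labeled_means(g, nuc_meas, ids),
                          _labeled_means(g, nuc, ids))
        mean_c_full = np.where(cyto_area > 0, _labeled_means(g, cyto, ids),
                               np.nan)
        mean_c = np.where(cmeas_area > 0,
                          _labeled_means(g, cyto_meas, ids), mean_c_full)

    sat_level = policy.saturation_level
    if sat_level is None:
        sat_level = field.acq.saturation_level
    sat_counts = np.asarray(ndi.sum_labels(
        (np.asarray(field.gfp, dtype=float) >= sat_level).astype(float),
        cell, ids))

    h, w = cell.shape
    border_ids = np.unique(np.concatenate([
        cell[0, :], cell[-1, :], cell[:, 0], cell[:, -1]]))
    on_border = np.isin(ids, border_ids[border_ids > 0])

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((cyto_area > 0) & (mean_c > 0), mean_n / mean_c,
                         np.nan)

    df = pd.DataFrame({
        "well_id": field.well_id, "field_id": field.field_id,
        "cell_id": ids.astype(int),
        "nucleus_area_px": nuc_area.astype(int),
        "cytoplasm_area_px": cyto_area.astype(int),
        "mean_nuclear_intensity": mean_n,
        "mean_cytoplasmic_intensity": mean_c,
        "nc_ratio": ratio,
        "background": background,
        "too_small": nuc_area < policy.min_nucleus_area_px,
        "border": on_border & policy.exclude_border,
        "degenerate_cyto": cyto_area < policy.min_cytoplasm_area_px,
        "saturated": sat_counts > 0,
        "low_signal": ~((mean_c > policy.low_signal_mean)
                        & (mean_n > policy.low_signal_mean)),
    })
    df["qc_pass"] = ~df[list(QC_FLAGS)].any(axis=1)
    return df


def _empty_records(field: FieldImage) -> pd.DataFrame:
    cols = ["well_id", "field_id", "cell_id", "nucleus_area_px",
            "cytoplasm_area_px", "mean_nuclear_intensity",
            "mean_cytoplasmic_intensity", "nc_ratio", "background",
            *QC_FLAGS, "qc_pass"]
    return pd.DataFrame(columns=cols)


def filter_cells(records: pd.DataFrame,
                 flags: tuple[str, ...] = QC_FLAGS
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records carrying any disqualifying flag.

    Returns (kept, tally) where tally counts rejections per reason (a
    cell failing several checks is counted under each) plus the totals.
    kept + rejected = input.
    """
    if records.empty:
        return records, {f: 0 for f in flags} | {"kept": 0, "rejected": 0}
    bad = records[list(flags)].any(axis=1)
    tally = {f: int(records[f].sum()) for f in flags}
    tally["kept"] = int((~bad).sum())
    tally["rejected"] = int(bad.sum())
    return records[~bad].copy(), tally
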