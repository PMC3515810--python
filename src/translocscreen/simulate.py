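"""Synthetic screening data with per-cell ground truth.

Generates two-channel fluorescence fields (DNA stain + GFP-tagged
receptor) for whole plates, the matching plate layouts, well-value-level
shortcuts for statistical simulations, and qPCR Cq tables with planted
fold changes.  Every quantity the downstream stages estimate (cell
label maps, nuclear fractions, N/C ratios, amplification efficiencies)
is emitted as ground truth so the estimators can be scored exactly.

The receptor-translocation phenotype is modelled as a dose-dependent
partition of each cell's total GFP between nucleus and cytoplasm
following a Hill curve (see :class:`~translocscreen.models.TranslocationModel`):
a cell at nuclear fraction f with nucleus area A_n and cytoplasm area
A_c has true N/C intensity ratio (f/A_n) / ((1-f)/A_c).
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .errors import CapacityError, PlacementError, ValidationError
from .models import (AcquisitionSpec, CellModel, NoiseModel,
                     TranslocationModel)

__all__ = [
    "WellSpec", "PlateLayout", "FieldImage", "GroundTruth",
    "make_plate_layout", "simulate_field", "simulate_plate",
    "simulate_plate_values", "simulate_qpcr", "true_nc_ratio",
    "layout_to_frame", "layout_from_frame",
]

_ROW_LETTERS = string.ascii_uppercase


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    row: int
    col: int
    treatment_label: str
    treatment_class: str
    dose: float
    replicate_group: str


@dataclass(frozen=True)
class PlateLayout:
    rows: int
    cols: int
    wells: tuple[WellSpec, ...]

    def __post_init__(self):
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValidationError("well_ids must be unique")
        n_vehicle = sum(w.treatment_class == "vehicle" for w in self.wells)
        if n_vehicle < 4:
            raise ValidationError("layout needs >= 4 vehicle wells")
        sizes = {}
        for w in self.wells:
            sizes.setdefault(w.replicate_group, 0)
            sizes[w.replicate_group] += 1
        if len(set(sizes.values())) > 1:
            raise ValidationError("replicate groups must be balanced")

    def by_class(self, cls: str) -> list[WellSpec]:
        return [w for w in self.wells if w.treatment_class == cls]


@dataclass
class FieldImage:
    """One imaged field: co-registered DNA and GFP rasters + metadata."""

    dna: np.ndarray
    gfp: np.ndarray
    well_id: str
    field_id: int
    acq: AcquisitionSpec

    def __post_init__(self):
        if self.dna.shape != self.gfp.shape:
            raise ValidationError("DNA and GFP rasters must share a shape")


@dataclass
class GroundTruth:
    """Rendered label maps plus the per-cell truth table.

    ``cells`` columns: cell_id, true_nuclear_fraction, true_nc_ratio,
    total_gfp, nucleus_area_px, cytoplasm_area_px.
    """

    nucleus_label_map: np.ndarray
    cell_label_map: np.ndarray
    cells: pd.DataFrame


def true_nc_ratio(f: float, nucleus_area: float, cytoplasm_area: float) -> float:
    """Analytic N/C mean-intensity ratio for nuclear fraction ``f``."""
    if not 0 <= f < 1:
        raise ValidationError("nuclear fraction must lie in [0, 1)")
    return (f / nucleus_area) / ((1.0 - f) / cytoplasm_area)


def well_name(row: int, col: int) -> str:
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


# ---------------------------------------------------------------------------
# plate layout


def make_plate_layout(rows: int, cols: int, n_samples: int, n_replicates: int,
                      seed: int, *, sample_dose: float = 100.0,
                      positive_dose: float = 100.0,
                      sample_labels: list[str] | None = None) -> PlateLayout:
    """Balanced layout: 4 vehicle wells, 4 positive-control wells, and
    ``n_replicates`` wells for each of ``n_samples`` water samples.

    Control wells occupy the first column (vehicle in the top half,
    hormone positive controls below, mirroring a typical screening
    plate); sample wells are shuffled over the remaining positions with
    ``seed``.
    """
    capacity = rows * cols
    required = n_samples * n_replicates + 8
    if required > capacity:
        raise CapacityError(
            f"layout needs {required} wells (={n_samples} samples x "
            f"{n_replicates} replicates + 8 controls) but the plate has "
            f"only {capacity}")
    if sample_labels is None:
        sample_labels = [f"S{i + 1:02d}" for i in range(n_samples)]
    elif len(sample_labels) != n_samples:
        raise ValidationError("sample_labels length must equal n_samples")

    rng = np.random.default_rng(seed)
    positions = [(r, c) for c in range(cols) for r in range(rows)]
    control_pos = positions[:8]
    open_pos = positions[8:]
    order = rng.permutation(len(open_pos))[: n_samples * n_replicates]
    sample_pos = [open_pos[i] for i in sorted(order)]

    wells: list[WellSpec] = []
    for i, (r, c) in enumerate(control_pos[:4]):
        wells.append(WellSpec(well_name(r, c), r, c, "DMSO", "vehicle",
                              0.0, "DMSO"))
    for i, (r, c) in enumerate(control_pos[4:8]):
        wells.append(WellSpec(well_name(r, c), r, c, "CORT_100nM",
                              "positive_control", positive_dose, "CORT_100nM"))
    k = 0
    for label in sample_labels:
        for _ in range(n_replicates):
            r, c = sample_pos[k]
            wells.append(WellSpec(well_name(r, c), r, c, label, "sample",
                                  sample_dose, label))
            k += 1
    return PlateLayout(rows=rows, cols=cols, wells=tuple(wells))


def layout_to_frame(layout: PlateLayout) -> pd.DataFrame:
    return pd.DataFrame(
        [{"well_id": w.well_id, "row": w.row, "col": w.col,
          "treatment_label": w.treatment_label,
          "treatment_class": w.treatment_class, "dose": w.dose,
          "replicate_group": w.replicate_group} for w in layout.wells])


def layout_from_frame(df: pd.DataFrame, rows: int | None = None,
                      cols: int | None = None) -> PlateLayout:
    rows = int(rows if rows is not None else df["row"].max() + 1)
    cols = int(cols if cols is not None else df["col"].max() + 1)
    wells = tuple(
        WellSpec(str(r.well_id), int(r.row), int(r.col),
                 str(r.treatment_label), str(r.treatment_class),
                 float(r.dose), str(r.replicate_group))
        for r in df.itertuples())
    return PlateLayout(rows=rows, cols=cols, wells=wells)


# ---------------------------------------------------------------------------
# field rendering


def _irregular_radius(theta: np.ndarray, base_r: float, aspect: float,
                      phase: float, irregularity: float,
                      wobble_phases: np.ndarray) -> np.ndarray:
    """Radius of a perturbed ellipse as a function of polar angle."""
    ct, st = np.cos(theta - phase), np.sin(theta - phase)
    r_ell = base_r / np.sqrt((ct / aspect) ** 2 + (st * aspect) ** 2)
    wobble = (np.cos(2 * theta + wobble_phases[0])
              + 0.6 * np.cos(3 * theta + wobble_phases[1]))
    return r_ell * (1.0 + 0.4 * irregularity * wobble)


def _sample_truncated_normal(rng, mean, sd, lo):
    for _ in range(64):
        v = rng.normal(mean, sd)
        if v > lo:
            return v
    return max(mean, lo * 1.01)


def simulate_field(entry: WellSpec, acq: AcquisitionSpec, cells: CellModel,
                   transloc: TranslocationModel, noise: NoiseModel,
                   n_cells: int, seed, *, field_id: int = 0,
                   max_attempts_per_cell: int = 500
                   ) -> tuple[FieldImage, GroundTruth]:
    """Render one two-channel field for a well and return its ground truth.

    Cells are perturbed ellipses (nucleus strictly inside the cell
    footprint), placed by rejection sampling with no footprint overlap.
    Each cell's total GFP is split between nucleus and cytoplasm with
    the Hill fraction f(dose) spread uniformly over compartment pixels,
    then blurred, offset by background and corrupted with shot/read
    noise per the :class:`NoiseModel`.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = acq.field_height_px, acq.field_width_px
    nuc_labels = np.zeros((h, w), dtype=np.int32)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    f = float(transloc.fraction(entry.dose))

    records = []
    for cid in range(1, n_cells + 1):
        r_cell = _sample_truncated_normal(rng, *cells.cell_radius_px, 3.0)
        r_nuc = _sample_truncated_normal(rng, *cells.nucleus_radius_px, 2.0)
        r_nuc = min(r_nuc, 0.75 * r_cell)
        aspect = rng.uniform(0.85, 1.18)
        phase = rng.uniform(0, np.pi)
        wobble = rng.uniform(0, 2 * np.pi, size=(2, 2))
        # pad keeps whole footprints inside the field so truth areas are exact
        pad = int(np.ceil(r_cell * (1 + 0.5 * cells.shape_irregularity) / min(aspect, 1.0))) + 2
        if 2 * pad >= min(h, w):
            raise PlacementError("cell radius too large for the field")
        placed = False
        for _ in range(max_attempts_per_cell):
            cy = rng.integers(pad, h - pad)
            cx = rng.integers(pad, w - pad)
            yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1]
            theta = np.arctan2(yy, xx)
            rho = np.hypot(yy, xx)
            cell_mask = rho <= _irregular_radius(
                theta, r_cell, aspect, phase, cells.shape_irregularity, wobble[0])
            nuc_mask = rho <= _irregular_radius(
                theta, r_nuc, aspect, phase, 0.6 * cells.shape_irregularity, wobble[1])
            nuc_mask &= cell_mask
            sl = (slice(cy - pad, cy + pad + 1), slice(cx - pad, cx + pad + 1))
            if np.any(cell_labels[sl][cell_mask]):
                continue
            cell_labels[sl][cell_mask] = cid
            nuc_labels[sl][nuc_mask] = cid
            a_n = int(nuc_mask.sum())
            a_c = int(cell_mask.sum()) - a_n
            records.append({
                "cell_id": cid, "true_nuclear_fraction": f,
                "true_nc_ratio": true_nc_ratio(f, a_n, a_c),
                "total_gfp": _sample_truncated_normal(rng, *cells.total_gfp, 0.0),
                "dna_intensity": _sample_truncated_normal(
                    rng, *cells.dna_stain_intensity, 0.0),
                "nucleus_area_px": a_n, "cytoplasm_area_px": a_c,
            })
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {cid}/{n_cells} after "
                f"{max_attempts_per_cell} attempts; reduce n_cells or "
                "enlarge the field")

    truth = pd.DataFrame(records)

    dna = np.zeros((h, w), dtype=float)
    gfp = np.zeros((h, w), dtype=float)
    for rec in records:
        cid = rec["cell_id"]
        nuc = nuc_labels == cid
        cyt = (cell_labels == cid) & ~nuc
        dna[nuc] += rec["dna_intensity"]
        g = rec["total_gfp"]
        gfp[nuc] += f * g / rec["nucleus_area_px"]
        gfp[cyt] += (1.0 - f) * g / rec["cytoplasm_area_px"]

    dna = _apply_noise(dna, noise, rng, acq)
    gfp = _apply_noise(gfp, noise, rng, acq)
    img = FieldImage(dna=dna, gfp=gfp, well_id=entry.well_id,
                     field_id=field_id, acq=acq)
    gt = GroundTruth(nucleus_label_map=nuc_labels,
                     cell_label_map=cell_labels, cells=truth)
    return img, gt


def _apply_noise(expected: np.ndarray, noise: NoiseModel, rng,
                 acq: AcquisitionSpec) -> np.ndarray:
    img = expected
    if noise.psf_sigma_px > 0:
        img = ndi.gaussian_filter(img, noise.psf_sigma_px)
    img = img + noise.background_level
    if noise.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, acq.saturation_level)
    dtype = np.uint8 if acq.bit_depth == 8 else np.uint16
    return img.astype(dtype)


def simulate_plate(layout: PlateLayout, acq: AcquisitionSpec,
                   cells: CellModel, transloc: TranslocationModel,
                   noise: NoiseModel, seed: int, *, n_cells: int = 50,
                   cell_count_jitter: float = 0.1
                   ) -> list[tuple[str, int, FieldImage, GroundTruth]]:
    """Simulate every field of every well in ``layout``.

    Per-field seeds are spawned deterministically from the master seed,
    so any field can be re-rendered in isolation and two runs with the
    same seed are bit-identical.  Cell counts per field are jittered
    around ``n_cells`` (Poisson-like plating variability).
    """
    out = []
    for wi, entry in enumerate(layout.wells):
        for fi in range(acq.fields_per_well):
            ss = np.random.SeedSequence([int(seed), wi, fi])
            count_rng = np.random.default_rng(ss.spawn(1)[0])
            n = max(1, int(round(n_cells * (1 + cell_count_jitter
                                            * count_rng.standard_normal()))))
            img, gt = simulate_field(entry, acq, cells, transloc, noise,
                                     n, ss, field_id=fi)
            out.append((entry.well_id, fi, img, gt))
    return out


# ---------------------------------------------------------------------------
# well-value-level simulation (statistics without images)


def simulate_plate_values(layout: PlateLayout, seed: int, *,
                          baseline: float = 1.0, well_sd: float = 0.05,
                          effects: dict[str, float] | None = None
                          ) -> pd.DataFrame:
    """Per-well normalized-translocation values drawn directly.

    Bypasses image rendering: each well's value is
    ``baseline + effects.get(treatment_label, 0) + N(0, well_sd)``.
    Used for large statistical simulations (type-I error, power) where
    only the well-level distribution matters.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    n = len(layout.wells)
    shift = np.array([effects.get(w.treatment_label, 0.0)
                      for w in layout.wells])
    return pd.DataFrame({
        "well_id": [w.well_id for w in layout.wells],
        "row": [w.row for w in layout.wells],
        "col": [w.col for w in layout.wells],
        "treatment_label": [w.treatment_label for w in layout.wells],
        "treatment_class": [w.treatment_class for w in layout.wells],
        "dose": [w.dose for w in layout.wells],
        "value": baseline + shift + rng.normal(0.0, well_sd, n),
    })


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(genes: list[str],
                  conditions: list[tuple[str, float | dict[str, float]]],
                  reference_gene: str, *, vehicle_label: str = "DMSO",
                  n_replicates: int = 4, dilution_points: int = 5,
                  efficiency: float = 1.0, cq_noise_sd: float = 0.0,
                  seed: int = 0, base_cq: float = 20.0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic Cq tables with planted fold changes plus dilution series.

    The amplification model is ``Cq = Cq0 - log(q) / log(1 + E)`` with
    efficiency ``E`` (E = 1 is perfect doubling, giving the classic
    -3.32 cycles per 10-fold template step).  The reference gene's fold
    change is pinned at 1 in every condition; target-gene folds come
    from ``conditions`` entries, either one number for all targets or a
    per-gene dict.

    Returns ``(cq_table, dilution_table)`` with columns
    (gene, condition, replicate, cq) and (gene, log10_quantity, cq).
    """
    if not 0 < efficiency <= 1:
        raise ValidationError("efficiency must lie in (0, 1]")
    if dilution_points < 3:
        raise ValidationError("dilution_points must be >= 3")
    if reference_gene not in genes:
        raise ValidationError("reference_gene must be listed in genes")
    labels = [c[0] for c in conditions]
    if vehicle_label not in labels:
        raise ValidationError("conditions must include the vehicle label")

    rng = np.random.default_rng(seed)
    slope_factor = 1.0 / np.log(1.0 + efficiency)  # cycles per ln(quantity)
    gene_cq0 = {g: base_cq + 1.5 * i for i, g in enumerate(genes)}

    cq_rows = []
    for label, fold_spec in conditions:
        for g in genes:
            if g == reference_gene:
                fold = 1.0
            elif isinstance(fold_spec, dict):
                fold = float(fold_spec.get(g, 1.0))
            else:
                fold = float(fold_spec)
            if fold <= 0:
                raise ValidationError(
                    f"true fold change must be positive (got {fold} for "
                    f"{g} in {label})")
            for rep in range(1, n_replicates + 1):
                cq = gene_cq0[g] - np.log(fold) * slope_factor
                if cq_noise_sd > 0:
                    cq += rng.normal(0.0, cq_noise_sd)
                cq_rows.append({"gene": g, "condition": label,
                                "replicate": rep, "cq": cq})

    dil_rows = []
    for g in genes:
        for k in range(dilution_points):
            log10_q = -float(k)  # 10-fold serial dilution from undiluted
            cq = gene_cq0[g] - log10_q * np.log(10.0) * slope_factor
            if cq_noise_sd > 0:
                cq += rng.normal(0.0, cq_noise_sd)
            dil_rows.append({"gene": g, "log10_quantity": log10_q, "cq": cq})

    return pd.DataFrame(cq_rows), pd.DataFrame(dil_rows)
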