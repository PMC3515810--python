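"""qPCR relative quantification via standard curves.

Quantities are interpolated from per-gene standard curves fitted to
10-fold serial dilution series (Cq vs log10 template quantity), then
normalized to a reference gene (beta-Actin / GAPDH style) and expressed
as fold change relative to the vehicle (DMSO) condition, mean +/- SEM
across replicates.  A ddCt mode (assumes perfect efficiency for every
gene) is provided for comparison.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CurveError, ValidationError

__all__ = ["StandardCurve", "fit_standard_curve", "relative_expression"]


@dataclass(frozen=True)
class StandardCurve:
    """Calibration line Cq = slope * log10(quantity) + intercept.

    ``efficiency`` = 10^(-1/slope) - 1; a perfect-doubling assay has
    slope -3.3219 and efficiency 1.0.
    """

    gene: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    cq_min: float
    cq_max: float

    def quantity(self, cq) -> np.ndarray:
        """Template quantity for a Cq (inverse of the calibration line)."""
        return 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept)
                        / self.slope)


def fit_standard_curve(dilutions: pd.DataFrame, gene: str | None = None
                       ) -> StandardCurve:
    """Least-squares calibration from a dilution series.

    ``dilutions`` needs columns ``log10_quantity`` and ``cq`` (and
    ``gene`` when the frame holds several genes and ``gene`` is given).
    Requires >= 3 points spanning >= 2 log10 units; a non-negative
    slope indicates mislabeled dilutions and raises :class:`CurveError`.
    """
    df = dilutions
    if gene is not None and "gene" in df.columns:
        df = df[df["gene"] == gene]
    if len(df) < 3:
        raise ValidationError("standard curve needs >= 3 dilution points")
    x = df["log10_quantity"].to_numpy(dtype=float)
    y = df["cq"].to_numpy(dtype=float)
    if x.max() - x.min() < 2:
        raise ValidationError("dilution series must span >= 2 log10 units")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise CurveError(
            f"standard curve slope {fit.slope:.3g} is not negative; "
            "check the dilution labels")
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    name = gene if gene is not None else str(df["gene"].iloc[0]) \
        if "gene" in df.columns else "?"
    return StandardCurve(gene=name, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         efficiency=float(eff),
                         r_squared=float(fit.rvalue**2),
                         cq_min=float(y.min()), cq_max=float(y.max()))


def relative_expression(cq_table: pd.DataFrame,
                        curves: dict[str, StandardCurve],
                        reference_gene: str, vehicle_label: str, *,
                        mode: str = "standard_curve") -> pd.DataFrame:
    """Fold change of each target gene vs vehicle, reference-normalized.

    Per replicate: quantity from the gene's standard curve, divided by
    the reference gene's quantity in the same (condition, replicate);
    fold change divides by the mean vehicle normalized quantity.
    Returns one row per (gene, condition): mean_fold_change, sem, n,
    and an ``extrapolated`` flag when any Cq fell outside its curve's
    calibrated range.  ``mode='ddct'`` uses 2^-ddCt instead of curves.
    """
    if mode not in ("standard_curve", "ddct"):
        raise ValidationError("mode must be 'standard_curve' or 'ddct'")
    required = {"gene", "condition", "replicate", "cq"}
    if not required <= set(cq_table.columns):
        raise ValidationError(f"Cq table needs columns {sorted(required)}")
    genes = list(cq_table["gene"].unique())
    if reference_gene not in genes:
        raise ValidationError(f"reference gene {reference_gene} absent")
    if mode == "standard_curve":
        missing = [g for g in genes if g not in curves]
        if missing:
            raise ValidationError(f"no standard curve for genes: {missing}")

    df = cq_table.copy()
    if mode == "standard_curve":
        df["quantity"] = [
            float(curves[g].quantity(c)) for g, c in zip(df["gene"], df["cq"])]
        df["extrapolated"] = [
            not (curves[g].cq_min <= c <= curves[g].cq_max)
            for g, c in zip(df["gene"], df["cq"])]
        if df["extrapolated"].any():
            n = int(df["extrapolated"].sum())
            warnings.warn(f"{n} Cq value(s) outside the calibrated range; "
                          "quantities are extrapolated", stacklevel=2)
    else:
        df["quantity"] = 2.0 ** (-df["cq"])
        df["extrapolated"] = False

    ref = df[df["gene"] == reference_gene].set_index(
        ["condition", "replicate"])["quantity"]
    targets = df[df["gene"] != reference_gene].copy()
    idx = pd.MultiIndex.from_frame(targets[["condition", "replicate"]])
    missing_ref = ~idx.isin(ref.index)
    if missing_ref.any():
        raise ValidationError(
            "reference gene missing for some (condition, replicate) pairs")
    targets["norm_quantity"] = targets["quantity"].to_numpy() \
        / ref.loc[idx].to_numpy()

    rows = []
    for gene, gdf in targets.groupby("gene"):
        veh = gdf[gdf["condition"] == vehicle_label]["norm_quantity"]
        if veh.empty:
            raise ValidationError(
                f"vehicle condition {vehicle_label!r} absent for {gene}")
        ref_mean = veh.mean()
        for cond, cdf in gdf.groupby("condition"):
            fold = cdf["norm_quantity"] / ref_mean
            rows.append({
                "gene": gene, "condition": cond,
                "mean_fold_change": float(fold.mean()),
                "sem": float(fold.std(ddof=1) / np.sqrt(len(fold)))
                       if len(fold) > 1 else np.nan,
                "n_replicates": int(len(fold)),
                "extrapolated": bool(cdf["extrapolated"].any()),
            })
    return pd.DataFrame(rows)


def expression_fold_values(cq_table: pd.DataFrame,
                           curves: dict[str, StandardCurve],
                           reference_gene: str, vehicle_label: str
                           ) -> pd.DataFrame:
    """Per-replicate fold changes (long format), for significance testing.

    Output columns: gene, condition, replicate, fold_change.  Feeding
    these per-gene into the Dunnett machinery of
    :mod:`translocscreen.screen` reproduces the many-to-one fold-change
    significance calls (families are per-gene).
    """
    df = cq_table.copy()
    df["quantity"] = [
        float(curves[g].quantity(c)) for g, c in zip(df["gene"], df["cq"])]
    ref = df[df["gene"] == reference_gene].set_index(
        ["condition", "replicate"])["quantity"]
    targets = df[df["gene"] != reference_gene].copy()
    idx = pd.MultiIndex.from_frame(targets[["condition", "replicate"]])
    targets["norm_quantity"] = targets["quantity"].to_numpy() \
        / ref.loc[idx].to_numpy()
    out = []
    for gene, gdf in targets.groupby("gene"):
        ref_mean = gdf[gdf["condition"] == vehicle_label]["norm_quantity"].mean()
        for r in gdf.itertuples():
            out.append({"gene": gene, "condition": r.condition,
                        "replicate": r.replicate,
                        "fold_change": r.norm_quantity / ref_mean})
    return pd.DataFrame(out)
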