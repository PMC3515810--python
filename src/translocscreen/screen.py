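"""Plate-level screening statistics.

Cells are pooled to wells, wells normalized to the plate's vehicle
(DMSO) controls, and hits called by the classical two-step
procedure for many-to-one screens: a one-way ANOVA gate at P < 0.05
followed by Dunnett's multiple comparison of every treatment against
the vehicle group, with hits tiered at adjusted P < 0.05 and P < 0.01.

Dunnett's critical value d solves  P(max_i |T_i| <= d) = 1 - alpha
where (T_1..T_k) follow the equicorrelated multivariate t distribution
of the k treatment-vs-control contrasts, correlation
rho_ij = lambda_i lambda_j with lambda_i = sqrt(n_i / (n_i + n_0)).
The probability is evaluated by 2-D Gauss quadrature over the shared
control variate (Gauss-Hermite) and the studentizing chi variable
(Gauss-Legendre on the scaled-chi density), conditional on which the
T_i are independent normals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr

from .errors import GateError, NormalizationError, PrecisionError, ValidationError
from .simulate import PlateLayout, layout_to_frame

__all__ = [
    "DunnettSpec", "AnovaResult", "aggregate_wells", "normalize_plate",
    "anova_gate", "dunnett_critical", "dunnett_max_abs_cdf", "dunnett_test",
    "dose_response_summary", "heatmap_matrix",
]

TIERS = ("negative", "p05", "p01")


# ---------------------------------------------------------------------------
# well aggregation and normalization


def aggregate_wells(cell_records: pd.DataFrame, layout: PlateLayout | pd.DataFrame,
                    *, min_cells_per_well: int = 10,
                    statistic: str = "mean",
                    pooling: str = "cells") -> pd.DataFrame:
    """Pool kept cells to one summary row per well.

    With ``pooling='cells'`` (default) cells from all fields of a well
    are pooled before averaging; ``pooling='fields'`` averages per-field
    values first and then averages those (the two agree when fields
    contribute equal cell counts).  Wells with fewer kept cells than
    ``min_cells_per_well`` are flagged (``usable = False``) and excluded
    from downstream statistics.  Wells present in the layout but absent
    from the records (e.g. blank after QC) appear with
    ``n_cells_kept = 0``.
    """
    ldf = layout if isinstance(layout, pd.DataFrame) else layout_to_frame(layout)
    known = set(ldf["well_id"])
    offenders = sorted(set(cell_records["well_id"]) - known)
    if offenders:
        raise ValidationError(
            f"cell records reference wells missing from the layout: {offenders}")
    agg = statistic
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    if pooling not in ("cells", "fields"):
        raise ValidationError("pooling must be 'cells' or 'fields'")

    grouped = cell_records.groupby("well_id")["nc_ratio"]
    if pooling == "fields":
        per_field = cell_records.groupby(["well_id", "field_id"])[
            "nc_ratio"].agg(agg)
        center = per_field.groupby("well_id").mean()
    else:
        center = grouped.agg(agg)
    summ = pd.DataFrame({
        "n_cells_kept": grouped.size(),
        "mean_nc_ratio": center,
        "sd": grouped.std(ddof=1),
    })
    out = ldf.merge(summ, left_on="well_id", right_index=True, how="left")
    out["n_cells_kept"] = out["n_cells_kept"].fillna(0).astype(int)
    out["sem"] = out["sd"] / np.sqrt(out["n_cells_kept"].clip(lower=1))
    out["usable"] = out["n_cells_kept"] >= min_cells_per_well
    return out


def normalize_plate(summaries: pd.DataFrame,
                    plate_col: str | None = None) -> pd.DataFrame:
    """Divide each well's mean N/C ratio by its plate's vehicle mean.

    The vehicle reference is the mean of usable vehicle-well means, so
    the vehicle group's mean normalized translocation is exactly 1 on
    every plate.  With ``plate_col`` set, plates normalize independently.
    """
    def _one(df: pd.DataFrame) -> pd.DataFrame:
        veh = df[(df["treatment_class"] == "vehicle") & df["usable"]]
        if veh.empty:
            raise NormalizationError(
                "no usable vehicle wells; plate cannot be normalized")
        ref = veh["mean_nc_ratio"].mean()
        if not ref > 0:
            raise NormalizationError("vehicle mean N/C ratio must be positive")
        out = df.copy()
        out["normalized_translocation"] = out["mean_nc_ratio"] / ref
        return out

    if plate_col is None:
        return _one(summaries)
    return summaries.groupby(plate_col, group_keys=False)[summaries.columns] \
                    .apply(_one)


# ---------------------------------------------------------------------------
# ANOVA gate


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int
    zero_within_variance: bool = False

    @property
    def passed(self) -> bool:
        return self.p_value < 0.05


def anova_gate(summaries: pd.DataFrame, *,
               value_col: str = "normalized_translocation",
               group_col: str = "treatment_label") -> AnovaResult:
    """One-way fixed-effects ANOVA on per-well values across treatments.

    Groups with fewer than two usable wells are excluded with a
    warning.  If every group is internally constant but groups differ
    (the noise-free limit), F is infinite and p reported as 0 with the
    ``zero_within_variance`` flag set.
    """
    df = summaries[summaries["usable"]] if "usable" in summaries else summaries
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in df.groupby(group_col) if len(g) >= 2]
    n_dropped = df[group_col].nunique() - len(groups)
    if n_dropped:
        warnings.warn(f"{n_dropped} group(s) with < 2 wells excluded from "
                      "the ANOVA gate", stacklevel=2)
    if len(groups) < 2:
        raise GateError("ANOVA gate needs >= 2 groups with >= 2 wells each")

    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within == 0:
        means = np.array([g.mean() for g in groups])
        differ = np.ptp(means) > 0
        return AnovaResult(np.inf if differ else 0.0,
                           0.0 if differ else 1.0, k - 1, n_tot - k,
                           zero_within_variance=True)
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(float(f_stat), float(p), k - 1, n_tot - k)


# ---------------------------------------------------------------------------
# Dunnett many-to-one machinery


@dataclass(frozen=True)
class DunnettSpec:
    """Design of a k-vs-control Dunnett comparison.

    ``n_treatments`` are the treatment group sizes n_1..n_k,
    ``n_control`` is n_0; the residual df is the classical one-way
    value nu = sum(n_i) - (k + 1) unless overridden (e.g. when extra
    groups on the plate contribute to the pooled variance).
    """

    n_control: int
    n_treatments: tuple[int, ...]
    alpha: float = 0.05
    two_sided: bool = True
    df_override: int | None = None

    def __post_init__(self):
        if self.n_control < 2 or any(n < 2 for n in self.n_treatments):
            raise ValidationError("all group sizes must be >= 2")
        if not self.n_treatments:
            raise ValidationError("need at least one treatment group")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.n_treatments)

    @property
    def df(self) -> int:
        if self.df_override is not None:
            return self.df_override
        return self.n_control + sum(self.n_treatments) - (self.k + 1)

    @property
    def lambdas(self) -> np.ndarray:
        n = np.asarray(self.n_treatments, dtype=float)
        return np.sqrt(n / (n + self.n_control))


def _chi_nodes(df: int, n_nodes: int = 96):
    """Gauss-Legendre nodes/weights for s = chi_df/sqrt(df) on (0, s_hi]."""
    s_hi = float(np.sqrt(stats.chi2.ppf(1 - 1e-14, df) / df))
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    s = 0.5 * s_hi * (x + 1.0)
    w = 0.5 * s_hi * w
    # density of s: 2 (df/2)^{df/2} / Gamma(df/2) s^{df-1} exp(-df s^2 / 2)
    logpdf = (np.log(2.0) + 0.5 * df * np.log(0.5 * df) - gammaln(0.5 * df)
              + (df - 1) * np.log(s) - 0.5 * df * s**2)
    return s, w * np.exp(logpdf)


def _hermite_nodes(n_nodes: int = 80):
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def dunnett_max_abs_cdf(q, spec: DunnettSpec, *, n_nodes: int = 96):
    """P(max_i |T_i| <= q) (or one-sided max T_i) for the Dunnett statistics.

    Vectorized over ``q``.  Conditional on the control variate z and
    the pooled-variance scale s, the T_i are independent, so the joint
    CDF is a product of normal CDFs integrated over (z, s).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    lam = spec.lambdas
    gam = np.sqrt(1.0 - lam**2)
    s, ws = _chi_nodes(spec.df, n_nodes)
    z, wz = _hermite_nodes(max(64, n_nodes - 16))

    # conditional independence: product over comparisons collapses to a
    # power for each distinct lambda (all equal in a balanced design)
    lam_u, counts = np.unique(lam, return_counts=True)
    gam_u = np.sqrt(1.0 - lam_u**2)
    qs = q[:, None, None] * s[None, :, None]   # (nq, ns, 1) after bcast
    prod = np.ones((len(q), len(s), len(z)))
    for lu, gu, c in zip(lam_u, gam_u, counts):
        zz = lu * z[None, None, :]
        upper = (qs + zz) / gu
        if spec.two_sided:
            term = ndtr(upper) - ndtr((-qs + zz) / gu)
        else:
            term = ndtr(upper)
        prod *= term ** c
    inner = prod @ wz                          # (nq, ns)
    out = inner @ ws                           # (nq,)
    return np.clip(out, 0.0, 1.0)


def dunnett_critical(spec: DunnettSpec, *, tol: float = 1e-8,
                     method: str = "auto") -> float:
    """Critical value d with P(max_i |T_i| <= d) = 1 - alpha.

    For k = 1 the statistic is an ordinary Student t, so the critical
    value reduces to the t quantile; ``method='quadrature'`` forces the
    numeric path even then (used to verify the quadrature against the
    analytic degeneracy).  Bracketing uses the single-comparison t
    quantile below and the Bonferroni bound above.
    """
    if method not in ("auto", "quadrature"):
        raise ValidationError("method must be 'auto' or 'quadrature'")
    a = spec.alpha
    if spec.k == 1 and method == "auto":
        return float(stats.t.ppf(1 - a / 2, spec.df) if spec.two_sided
                     else stats.t.ppf(1 - a, spec.df))
    per = a / max(spec.k, 2)
    lo = 0.999 * float(stats.t.ppf(1 - a / 2, spec.df) if spec.two_sided
                       else stats.t.ppf(1 - a, spec.df))
    hi = 1.001 * float(stats.t.ppf(1 - per / 2, spec.df) if spec.two_sided
                       else stats.t.ppf(1 - per, spec.df))

    def fun(d):
        return float(dunnett_max_abs_cdf(d, spec)[0]) - (1.0 - a)

    flo, fhi = fun(lo), fun(hi)
    if flo > 0 or fhi < 0:  # widen bracket defensively
        lo, hi = 0.5 * lo, 1.5 * hi
        flo, fhi = fun(lo), fun(hi)
        if flo > 0 or fhi < 0:
            raise PrecisionError("failed to bracket the Dunnett critical value")
    return float(brentq(fun, lo, hi, xtol=tol))


def dunnett_pvalues(t_stats, spec: DunnettSpec) -> np.ndarray:
    """Adjusted p-values: p_i = P(max_j |T_j| >= |t_i|) under the null."""
    t = np.atleast_1d(np.asarray(t_stats, dtype=float))
    q = np.abs(t) if spec.two_sided else t
    p = np.ones_like(q)
    finite = np.isfinite(q)
    if spec.two_sided:
        p[finite] = 1.0 - dunnett_max_abs_cdf(q[finite], spec)
    else:
        pos = finite & (q > -np.inf)
        p[pos] = 1.0 - dunnett_max_abs_cdf(q[pos], spec)
    p[np.isposinf(q)] = 0.0
    return np.clip(p, 0.0, 1.0)


def dunnett_test(summaries: pd.DataFrame, *, alpha: float = 0.05,
                 two_sided: bool = True, gate: AnovaResult | None = None,
                 value_col: str = "normalized_translocation",
                 vehicle_class: str = "vehicle") -> pd.DataFrame:
    """Hit table: every treatment compared to the vehicle group.

    T_i = (mean_i - mean_0) / (s_pooled * sqrt(1/n_i + 1/n_0)) with the
    pooled within-group variance from all usable groups on the plate.
    Tiers (p05 / p01) are assigned only when the ANOVA gate passed;
    otherwise every tier is ``negative`` and adjusted p is NaN (the
    not-evaluated marker).  The vehicle row is tiered negative by
    definition.  ``direction`` records whether the group mean lies
    above (activity) or below the vehicle mean.
    """
    df = summaries[summaries["usable"]] if "usable" in summaries else summaries
    veh = df[df["treatment_class"] == vehicle_class]
    if veh.empty:
        raise NormalizationError("no usable vehicle wells for Dunnett test")
    if gate is None:
        gate = anova_gate(summaries, value_col=value_col)

    groups = {lab: g[value_col].to_numpy(dtype=float)
              for lab, g in df.groupby("treatment_label")}
    veh_label = veh["treatment_label"].iloc[0]
    x0 = groups[veh_label]
    others = [(lab, v) for lab, v in groups.items()
              if lab != veh_label and len(v) >= 2]
    if len(x0) < 2 or not others:
        raise GateError("Dunnett test needs >= 2 wells in vehicle and >= 1 "
                        "treatment group")

    all_vals = [x0] + [v for _, v in others]
    nu = sum(len(v) for v in all_vals) - len(all_vals)
    s2 = sum(((v - v.mean()) ** 2).sum() for v in all_vals) / nu
    spec = DunnettSpec(n_control=len(x0),
                       n_treatments=tuple(len(v) for _, v in others),
                       alpha=alpha, two_sided=two_sided, df_override=nu)

    diffs = np.array([v.mean() - x0.mean() for _, v in others])
    ses = np.array([np.sqrt(s2 * (1 / len(v) + 1 / len(x0)))
                    for _, v in others])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(ses > 0, diffs / ses,
                     np.where(diffs == 0, 0.0, np.inf * np.sign(diffs)))

    if gate.passed:
        p_adj = dunnett_pvalues(t, spec)
        tier = np.where(p_adj < 0.01, "p01",
                        np.where(p_adj < alpha, "p05", "negative"))
    else:
        p_adj = np.full(len(others), np.nan)
        tier = np.full(len(others), "negative", dtype=object)

    meta = df.drop_duplicates("treatment_label").set_index("treatment_label")
    rows = [{
        "treatment_label": veh_label,
        "treatment_class": vehicle_class,
        "dose": float(meta.loc[veh_label, "dose"]),
        "n_wells": len(x0), "group_mean": x0.mean(),
        "sem": x0.std(ddof=1) / np.sqrt(len(x0)),
        "t_stat": 0.0, "adjusted_p": np.nan, "tier": "negative",
        "direction": "none",
    }]
    for (lab, v), ti, pi, tri in zip(others, t, p_adj, tier):
        rows.append({
            "treatment_label": lab,
            "treatment_class": str(meta.loc[lab, "treatment_class"]),
            "dose": float(meta.loc[lab, "dose"]),
            "n_wells": len(v), "group_mean": v.mean(),
            "sem": v.std(ddof=1) / np.sqrt(len(v)),
            "t_stat": float(ti), "adjusted_p": float(pi),
            "tier": str(tri),
            "direction": "increase" if v.mean() > x0.mean()
                         else ("decrease" if v.mean() < x0.mean() else "none"),
        })
    out = pd.DataFrame(rows)
    out.attrs["anova_f"] = gate.f_stat
    out.attrs["anova_p"] = gate.p_value
    out.attrs["gate_passed"] = gate.passed
    return out


# ---------------------------------------------------------------------------
# dose-response and plate rendering


@dataclass
class DoseResponseResult:
    table: pd.DataFrame
    detection_threshold: float | None
    spearman_rho: float
    anova: AnovaResult


def dose_response_summary(summaries: pd.DataFrame, *, alpha: float = 0.05,
                          value_col: str = "normalized_translocation"
                          ) -> DoseResponseResult:
    """Dose ladder for one sample: per-dose mean, SEM, Dunnett p, and
    the lowest dose called significant (the detection threshold).

    Input must contain vehicle wells (dose 0) plus >= 3 replicated dose
    levels of one sample; unreplicated doses are excluded with a warning.
    Spearman's rho is computed between dose and the per-dose mean.
    """
    df = (summaries[summaries["usable"]] if "usable" in summaries
          else summaries).copy()
    sizes = df.groupby("treatment_label")["well_id"].count()
    single = sizes[sizes < 2].index
    if len(single):
        warnings.warn(f"unreplicated groups excluded: {sorted(single)}",
                      stacklevel=2)
        df = df[~df["treatment_label"].isin(single)]
    doses = df.loc[df["treatment_class"] != "vehicle", "dose"].unique()
    if len(doses) < 3:
        raise ValidationError("dose-response needs >= 3 replicated dose levels")

    gate = anova_gate(df, value_col=value_col)
    hits = dunnett_test(df, alpha=alpha, gate=gate, value_col=value_col)
    tab = hits[hits["treatment_class"] != "vehicle"] \
        .sort_values("dose").reset_index(drop=True)
    sig = tab[(tab["adjusted_p"] < alpha) & (tab["direction"] == "increase")]
    threshold = float(sig["dose"].min()) if not sig.empty else None
    rho = stats.spearmanr(tab["dose"], tab["group_mean"]).statistic
    return DoseResponseResult(table=tab, detection_threshold=threshold,
                              spearman_rho=float(rho), anova=gate)


def heatmap_matrix(summaries: pd.DataFrame, *, value: str = "normalized",
                   rows: int | None = None, cols: int | None = None
                   ) -> pd.DataFrame:
    """Plate-geometry matrix of a well statistic; empty wells are NaN."""
    col = {"raw_ratio": "mean_nc_ratio",
           "normalized": "normalized_translocation"}.get(value)
    if col is None:
        raise ValidationError("value must be 'raw_ratio' or 'normalized'")
    if summaries.duplicated(["row", "col"]).any():
        raise ValidationError("duplicate well coordinates in summaries")
    n_rows = int(rows if rows is not None else summaries["row"].max() + 1)
    n_cols = int(cols if cols is not None else summaries["col"].max() + 1)
    mat = np.full((n_rows, n_cols), np.nan)
    mat[summaries["row"].to_numpy(), summaries["col"].to_numpy()] = \
        summaries[col].to_numpy(dtype=float)
    import string
    return pd.DataFrame(mat, index=list(string.ascii_uppercase[:n_rows]),
                        columns=np.arange(1, n_cols + 1))


def render_heatmap(matrix: pd.DataFrame, path, *, title: str = "",
                   cmap: str = "viridis") -> None:
    """Write a plate heat-map image (wells colored by translocation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.45 * matrix.shape[1] + 1.5,
                                    0.45 * matrix.shape[0] + 1.2))
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="N/C ratio (vehicle-normalized)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
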