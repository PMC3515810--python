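"""Ground-truth benchmarks exercising the full pipeline.

Each function simulates data at documented study conditions, runs the
relevant pipeline stages from scratch, and returns the measured figures
of merit (segmentation fidelity, ratio recovery, error control, hit
recovery, qPCR recovery).  They are shared by the acceptance test suite
and the reproduction script.

Problem sizes are chosen so a full run completes in minutes on one
CPU: full-resolution 512-px fields for segmentation/ratio scoring, and
reduced 160-px single-field wells for the 285-well screening plates.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .models import (AcquisitionSpec, CellModel, NoiseModel, QCPolicy,
                     SegmentationParams, TranslocationModel)
from .qpcr import fit_standard_curve, relative_expression
from .quantify import filter_cells, measure_cells
from .screen import (DunnettSpec, aggregate_wells, anova_gate,
                     dose_response_summary, dunnett_critical, dunnett_test,
                     normalize_plate)
from .segment import segment_cytoplasm, segment_nuclei
from .simulate import (WellSpec, make_plate_layout, simulate_field,
                       simulate_plate, simulate_plate_values, simulate_qpcr)

#: mean nucleus area implied by the default CellModel radius (~10 px)
_DEFAULT_NUC_AREA = np.pi * 10.0**2


def snr_noise(snr: float, *, psf_sigma_px: float = 0.8) -> NoiseModel:
    """Shot-noise-limited noise model; SNR = sqrt(signal) at the stated
    signal level, with a 20-count background and no read noise."""
    return NoiseModel(background_level=20.0, read_noise_sd=0.0,
                      shot_noise=True, psf_sigma_px=psf_sigma_px)


def snr_cell_model(snr: float, fraction: float) -> CellModel:
    """CellModel whose nuclear GFP pixel signal is ~snr^2 counts at the
    given nuclear fraction, and whose DNA stain is snr^2 counts."""
    signal = snr**2
    total = signal * _DEFAULT_NUC_AREA / fraction
    return CellModel(total_gfp=(total, 0.1 * total),
                     dna_stain_intensity=(signal, 0.1 * signal))


def match_iou(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Best-overlap IoU per ground-truth object."""
    out = []
    for lab in np.unique(truth[truth > 0]):
        t = truth == lab
        votes = np.bincount(pred[t])
        votes[0] = 0
        if votes.sum() == 0:
            out.append(0.0)
            continue
        p = pred == votes.argmax()
        out.append(float((t & p).sum() / (t | p).sum()))
    return np.asarray(out)


# ---------------------------------------------------------------------------


def segmentation_fidelity(seed: int, *, n_fields: int = 10,
                          n_cells: int = 50, snr: float | None = None
                          ) -> dict[str, float]:
    """Nucleus count error and mean IoU over simulated fields.

    ``snr=None`` renders noise-free fields; otherwise shot-noise-limited
    fields at the requested SNR (DNA signal = snr^2 counts).
    """
    acq = AcquisitionSpec(fields_per_well=1)
    if snr is None:
        cells, noise = CellModel(), NoiseModel.noiseless()
    else:
        cells, noise = snr_cell_model(snr, 0.5), snr_noise(snr)
    params = SegmentationParams(border_policy="keep")
    entry = WellSpec("A01", 0, 0, "S01", "sample", 0.0, "S01")
    n_true = n_found = 0
    ious = []
    for i in range(n_fields):
        img, gt = simulate_field(entry, acq, cells, TranslocationModel(),
                                 noise, n_cells,
                                 np.random.SeedSequence([seed, i]))
        labels = segment_nuclei(img.dna, params)
        n_true += len(gt.cells)
        n_found += int(labels.max())
        ious.append(match_iou(labels, gt.nucleus_label_map))
    return {"count_error_rate": abs(n_found - n_true) / n_true,
            "mean_iou": float(np.concatenate(ious).mean()),
            "n_nuclei": n_true}


def ratio_recovery(seed: int, *, fractions=(0.3, 0.5, 0.7, 0.9),
                   snr: float = 20.0, fields_per_fraction: int = 3,
                   cells_per_field: int = 40) -> dict[float, float]:
    """Relative error of the per-well median N/C ratio vs analytic truth.

    For each planted nuclear fraction, one simulated well (>= 100 kept
    cells pooled over fields) is segmented and measured from scratch;
    the median measured ratio is compared with the median per-cell
    analytic ratio (f/A_n)/((1-f)/A_c).
    """
    acq = AcquisitionSpec(fields_per_well=1)
    out = {}
    for f in fractions:
        model = TranslocationModel(f_min=f, f_max=min(f + 0.05, 0.999))
        cells = snr_cell_model(snr, f)
        noise = snr_noise(snr)
        entry = WellSpec("A01", 0, 0, "S01", "sample", 0.0, "S01")
        measured, truth = [], []
        for i in range(fields_per_fraction):
            img, gt = simulate_field(
                entry, acq, cells, model, noise, cells_per_field,
                np.random.SeedSequence([seed, int(f * 1000), i]))
            nuc = segment_nuclei(img.dna)
            pair = segment_cytoplasm(img.gfp, nuc)
            kept, _ = filter_cells(measure_cells(img, pair))
            measured += list(kept["nc_ratio"])
            truth += list(gt.cells["true_nc_ratio"])
        out[f] = float(np.median(measured) / np.median(truth) - 1.0)
    return out


def normalization_identity(seed: int, *, n_plates: int = 5) -> float:
    """Max |vehicle-group mean normalized translocation - 1| over plates."""
    worst = 0.0
    for i in range(n_plates):
        layout = make_plate_layout(8, 12, 12, 4, seed=seed + i)
        values = simulate_plate_values(layout, seed=seed + i, well_sd=0.1)
        wells = _values_to_summaries(values)
        wells = normalize_plate(wells)
        veh = wells[wells["treatment_class"] == "vehicle"]
        worst = max(worst,
                    abs(float(veh["normalized_translocation"].mean()) - 1.0))
    return worst


def _values_to_summaries(values: pd.DataFrame) -> pd.DataFrame:
    df = values.rename(columns={"value": "mean_nc_ratio"}).copy()
    df["n_cells_kept"] = 100
    df["sd"] = np.nan
    df["sem"] = np.nan
    df["usable"] = True
    return df


def dunnett_k1_error() -> float:
    """|quadrature - Student t| for the single-comparison degeneracy."""
    spec = DunnettSpec(n_control=4, n_treatments=(4,))
    d = dunnett_critical(spec, method="quadrature")
    return abs(d - float(stats.t.ppf(0.975, spec.df)))


def dunnett_mc_agreement(seed: int, *, ks=(2, 4, 8), dfs=(6, 12, 30),
                         n_draws: int = 10**6) -> dict[str, float]:
    """Quadrature criticals vs the Monte-Carlo max-|T| oracle.

    Returns the worst absolute deviation and the worst deviation in MC
    standard errors across the (k, df) grid.
    """
    worst_abs = worst_se = 0.0
    for k in ks:
        for df in dfs:
            spec = DunnettSpec(n_control=4, n_treatments=(4,) * k,
                               df_override=df)
            d = dunnett_critical(spec)
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, k, df]))
            lam = np.sqrt(0.5)
            z0 = rng.standard_normal(n_draws)
            z = rng.standard_normal((n_draws, k))
            s = np.sqrt(rng.chisquare(df, n_draws) / df)
            m = np.abs(np.sqrt(1 - lam**2) * z
                       + lam * z0[:, None]).max(axis=1) / s
            q = float(np.quantile(m, 0.95))
            bw = m.std() * n_draws ** -0.2
            dens = np.mean(np.abs(m - q) < bw) / (2 * bw)
            se = float(np.sqrt(0.05 * 0.95 / n_draws) / dens)
            worst_abs = max(worst_abs, abs(d - q))
            worst_se = max(worst_se, abs(d - q) / se)
    return {"max_abs_diff": worst_abs, "max_diff_in_mc_se": worst_se}


def familywise_error_rate(seed: int, *, n_plates: int = 1000,
                          n_samples: int = 69, well_sd: float = 0.05
                          ) -> dict[str, float]:
    """FWER of the ANOVA-gated Dunnett screen on all-null plates.

    Well values are simulated directly (no images): every group draws
    from the vehicle distribution.  A plate counts as a familywise
    error if any sample is tiered positive.
    """
    layout = make_plate_layout(16, 18, n_samples, 4, seed=seed)
    hits = 0
    for i in range(n_plates):
        values = simulate_plate_values(layout, seed=np.random.SeedSequence(
            [seed, i]).generate_state(1)[0] % 2**31, well_sd=well_sd)
        wells = normalize_plate(_values_to_summaries(values))
        gate = anova_gate(wells)
        if not gate.passed:
            continue
        table = dunnett_test(wells, gate=gate)
        samp = table[table["treatment_class"] == "sample"]
        if (samp["tier"] != "negative").any():
            hits += 1
    rate = hits / n_plates
    return {"fwer": rate, "n_plates": n_plates,
            "binomial_se": float(np.sqrt(0.05 * 0.95 / n_plates))}


ACTIVE_LABELS = ("S05", "S13", "S21", "S29", "S37", "S45", "S53", "S61")


def hit_recovery(seed: int, *, n_seeds: int = 20, n_samples: int = 69,
                 field_px: int = 192, n_cells: int = 7
                 ) -> dict[str, float]:
    """End-to-end screen of the 69-sample / 8-active plate design.

    Each replicate renders, segments and measures every field of a
    285-well plate (reduced field size), then calls hits; planted
    actives receive a saturating dose (effect far above 5 pooled SD).
    Returns how many runs recovered exactly the planted set, plus total
    false positives / negatives over all runs.
    """
    acq = AcquisitionSpec(field_width_px=field_px, field_height_px=field_px,
                          fields_per_well=1)
    exact_runs = false_pos = false_neg = 0
    for i in range(n_seeds):
        run_seed = int(np.random.SeedSequence([seed, i])
                       .generate_state(1)[0] % 2**31)
        layout = make_plate_layout(16, 18, n_samples, 4, seed=run_seed,
                                   sample_dose=0.0)
        wells = []
        for w in layout.wells:
            dose = 100.0 if w.treatment_label in ACTIVE_LABELS else w.dose
            wells.append(replace(w, dose=dose))
        layout = type(layout)(layout.rows, layout.cols, tuple(wells))
        frames = []
        for wid, fid, img, _gt in simulate_plate(
                layout, acq, CellModel(), TranslocationModel(), NoiseModel(),
                run_seed, n_cells=n_cells):
            nuc = segment_nuclei(img.dna)
            pair = segment_cytoplasm(img.gfp, nuc)
            frames.append(measure_cells(img, pair))
        kept, _ = filter_cells(pd.concat(frames, ignore_index=True))
        summ = aggregate_wells(kept, layout, min_cells_per_well=3)
        summ = normalize_plate(summ)
        gate = anova_gate(summ)
        table = dunnett_test(summ, gate=gate)
        samp = table[table["treatment_class"] == "sample"]
        called = set(samp[(samp["tier"] != "negative")
                          & (samp["direction"] == "increase")]
                     ["treatment_label"])
        planted = set(ACTIVE_LABELS)
        false_pos += len(called - planted)
        false_neg += len(planted - called)
        exact_runs += called == planted
    return {"n_seeds": n_seeds, "exact_recovery_runs": exact_runs,
            "false_positives": false_pos, "false_negatives": false_neg}


def _dose_ladder_summary(seed: int, doses, model: TranslocationModel,
                         cells: CellModel, noise: NoiseModel,
                         field_px: int, n_cells: int):
    acq = AcquisitionSpec(field_width_px=field_px, field_height_px=field_px,
                          fields_per_well=1)
    rows, layout_rows = [], []
    idx = 0
    for label, dose, cls in ([("DMSO", 0.0, "vehicle")]
                             + [(f"d{d:g}", d, "sample") for d in doses]):
        for _rep in range(4):
            wid = f"W{idx:03d}"
            entry = WellSpec(wid, idx // 12, idx % 12, label, cls, dose,
                             label)
            img, _gt = simulate_field(
                entry, acq, cells, model, noise, n_cells,
                np.random.SeedSequence([seed, idx]))
            nuc = segment_nuclei(img.dna)
            pair = segment_cytoplasm(img.gfp, nuc)
            rows.append(measure_cells(img, pair))
            layout_rows.append({"well_id": wid, "row": idx // 12,
                                "col": idx % 12, "treatment_label": label,
                                "treatment_class": cls, "dose": dose,
                                "replicate_group": label})
            idx += 1
    kept, _ = filter_cells(pd.concat(rows, ignore_index=True))
    summ = aggregate_wells(kept, pd.DataFrame(layout_rows),
                           min_cells_per_well=3)
    return dose_response_summary(normalize_plate(summ))


def dose_response_check(seed: int, *, doses=(1.0, 3.0, 10.0, 30.0, 100.0),
                        field_px: int = 192, n_cells: int = 10
                        ) -> dict[str, float]:
    """Image-based dose ladders of one sample under a steep Hill model.

    Two ladders are rendered and pushed through the full pipeline:

    * a noise-free one (no detection noise, uniform cell geometry), on
      which the dose-response rank correlation is read out — the
      monotone Hill model must give Spearman rho = 1;
    * one under the default noise model, on which the lowest
      significant dose is compared with the planted detection
      threshold.  The Hill curve (ec50 8, coefficient 4) keeps doses
      below 10x essentially at baseline, so the planted threshold is
      the lowest dose raising the nuclear fraction > 5 points.
    """
    model = TranslocationModel(f_min=0.25, f_max=0.9, ec50=8.0, hill=4.0)
    planted = min(d for d in doses
                  if model.fraction(d) > model.f_min + 0.05)

    uniform_cells = CellModel(nucleus_radius_px=(10.0, 0.0),
                              cell_radius_px=(17.0, 0.0),
                              total_gfp=(250_000.0, 0.0),
                              dna_stain_intensity=(400.0, 0.0),
                              shape_irregularity=0.0)
    clean = _dose_ladder_summary(seed, doses, model, uniform_cells,
                                 NoiseModel.noiseless(), field_px, n_cells)
    noisy = _dose_ladder_summary(seed + 1, doses, model, CellModel(),
                                 NoiseModel(), field_px, n_cells)
    return {"spearman_rho": clean.spearman_rho,
            "detected_threshold": noisy.detection_threshold,
            "planted_threshold": float(planted)}


def qpcr_recovery(seed: int, *, folds=(0.5, 2.0, 5.0, 10.0),
                  cq_noise_sd: float = 0.15) -> dict[str, float]:
    """Standard-curve closed forms plus planted fold-change recovery.

    Runs a noise-free perfect-doubling dilution series (slope/efficiency
    closed forms), a noisy fold-recovery experiment (n = 4 replicates),
    and a planted rise-then-fall dose profile checked in rank order.
    """
    # closed-form: perfect doubling chemistry, noiseless
    _, dil0 = simulate_qpcr(["g", "ref"], [("DMSO", 1.0)], "ref",
                            efficiency=1.0, cq_noise_sd=0.0, seed=seed)
    curve0 = fit_standard_curve(dil0, "g")

    conds = [("DMSO", 1.0)] + [(f"F{f:g}", f) for f in folds]
    cq, dil = simulate_qpcr(["g", "ref"], conds, "ref",
                            cq_noise_sd=cq_noise_sd, n_replicates=4,
                            seed=seed)
    curves = {g: fit_standard_curve(dil, g) for g in ("g", "ref")}
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = relative_expression(cq, curves, "ref", "DMSO")
    est = expr.set_index("condition")["mean_fold_change"]
    max_err = max(abs(est[f"F{f:g}"] / f - 1.0) for f in folds)

    profile = {"d1": 1.2, "d10": 3.0, "d50": 8.0, "d100": 2.0}
    cq2, dil2 = simulate_qpcr(["g", "ref"],
                              [("DMSO", 1.0)] + list(profile.items()), "ref",
                              cq_noise_sd=0.05, seed=seed + 1)
    curves2 = {g: fit_standard_curve(dil2, g) for g in ("g", "ref")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr2 = relative_expression(cq2, curves2, "ref", "DMSO")
    est2 = expr2.set_index("condition")["mean_fold_change"]
    rank_ok = (sorted(profile, key=profile.get)
               == sorted(profile, key=est2.get))
    return {"slope": curve0.slope, "efficiency": curve0.efficiency,
            "max_fold_rel_error": float(max_err),
            "nonmonotonic_rank_preserved": bool(rank_ok)}
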