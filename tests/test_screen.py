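"""Well aggregation, vehicle normalization, ANOVA gate, dose-response,
plate heat-maps."""
import numpy as np
import pandas as pd
import pytest

import translocscreen as ts
from translocscreen.errors import GateError, NormalizationError, ValidationError
from translocscreen.screen import anova_gate, dose_response_summary, heatmap_matrix


def _cells(well_ratios: dict[str, list[float]]):
    rows = []
    for wid, ratios in well_ratios.items():
        for i, r in enumerate(ratios):
            rows.append({"well_id": wid, "field_id": 0, "cell_id": i,
                         "nc_ratio": r})
    return pd.DataFrame(rows)


def _layout(n_samples=1, seed=0):
    return ts.make_plate_layout(8, 12, n_samples, 4, seed=seed)


class TestAggregateWells:
    def test_mean_of_cells(self):
        lay = _layout()
        wid = lay.by_class("sample")[0].well_id
        cells = _cells({wid: [1.0, 2.0, 3.0]})
        out = ts.aggregate_wells(cells, lay, min_cells_per_well=2)
        row = out[out["well_id"] == wid].iloc[0]
        assert row["mean_nc_ratio"] == pytest.approx(2.0)
        assert row["n_cells_kept"] == 3

    def test_sparse_well_flagged_unusable(self):
        lay = _layout()
        wid = lay.by_class("sample")[0].well_id
        out = ts.aggregate_wells(_cells({wid: [1.0]}), lay,
                                 min_cells_per_well=5)
        assert not out[out["well_id"] == wid]["usable"].iloc[0]

    def test_fields_pooled_within_well(self):
        lay = _layout()
        wid = lay.by_class("vehicle")[0].well_id
        cells = _cells({wid: [1.0, 2.0]})
        cells.loc[1, "field_id"] = 1  # second field, same well
        out = ts.aggregate_wells(cells, lay, min_cells_per_well=1)
        assert out[out["well_id"] == wid]["mean_nc_ratio"].iloc[0] \
            == pytest.approx(1.5)

    def test_pooling_orders_agree_for_balanced_fields(self):
        """Cells-first and fields-first averaging coincide when every
        field contributes the same number of cells, and differ when
        fields are unbalanced."""
        lay = _layout()
        wid = lay.by_class("vehicle")[0].well_id
        cells = _cells({wid: [1.0, 2.0, 3.0, 5.0]})
        cells["field_id"] = [0, 0, 1, 1]
        a = ts.aggregate_wells(cells, lay, min_cells_per_well=1)
        b = ts.aggregate_wells(cells, lay, min_cells_per_well=1,
                               pooling="fields")
        assert a[a["well_id"] == wid]["mean_nc_ratio"].iloc[0] \
            == pytest.approx(b[b["well_id"] == wid]["mean_nc_ratio"].iloc[0])
        cells["field_id"] = [0, 0, 0, 1]  # unbalanced: 3 + 1 cells
        c = ts.aggregate_wells(cells, lay, min_cells_per_well=1,
                               pooling="fields")
        assert c[c["well_id"] == wid]["mean_nc_ratio"].iloc[0] \
            == pytest.approx((2.0 + 5.0) / 2)

    def test_unknown_well_is_an_error(self):
        with pytest.raises(ValidationError, match="ZZ99"):
            ts.aggregate_wells(_cells({"ZZ99": [1.0]}), _layout())


class TestNormalizePlate:
    def test_vehicle_mean_is_exactly_one(self, wells_factory):
        wells = wells_factory({"DMSO": [1.1, 0.9, 1.0, 1.0],
                               "S01": [3.0, 3.1, 2.9, 3.0]})
        out = ts.normalize_plate(wells)
        veh = out[out["treatment_class"] == "vehicle"]
        assert veh["normalized_translocation"].mean() == pytest.approx(1.0,
                                                                       abs=1e-12)

    def test_scaling_against_vehicle(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0, 1.0, 1.0, 1.0],
                               "S01": [3.0, 3.0, 3.0, 3.0]})
        out = ts.normalize_plate(wells)
        assert np.allclose(out[out["treatment_label"] == "S01"]
                           ["normalized_translocation"], 3.0)

    def test_plates_normalized_independently(self, wells_factory):
        a = wells_factory({"DMSO": [2.0, 2.0, 2.0, 2.0], "S01": [4.0] * 4})
        b = wells_factory({"DMSO": [0.5, 0.5, 0.5, 0.5], "S01": [2.0] * 4})
        a["plate"], b["plate"] = "P1", "P2"
        out = ts.normalize_plate(pd.concat([a, b], ignore_index=True),
                                 plate_col="plate")
        for _, grp in out.groupby("plate"):
            veh = grp[grp["treatment_class"] == "vehicle"]
            assert veh["normalized_translocation"].mean() \
                == pytest.approx(1.0, abs=1e-12)

    def test_no_vehicle_rejects_plate(self, wells_factory):
        wells = wells_factory({"S01": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(NormalizationError):
            ts.normalize_plate(wells)


class TestAnovaGate:
    def test_identical_constant_groups_degenerate_path(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0] * 4, "S01": [2.0] * 4})
        res = anova_gate(wells)
        assert res.zero_within_variance and res.p_value == 0.0

    def test_flat_constant_groups_not_significant(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0] * 4, "S01": [1.0] * 4})
        res = anova_gate(wells)
        assert res.zero_within_variance and res.p_value == 1.0

    def test_separated_groups_reject(self, wells_factory):
        wells = wells_factory({"DMSO": [0.0, 1e-4, -1e-4, 0.0],
                               "S01": [1.0, 1.0001, 0.9999, 1.0]})
        res = anova_gate(wells)
        assert res.p_value < 1e-3

    def test_matches_scipy_f_oneway(self, wells_factory):
        rng = np.random.default_rng(0)
        wells = wells_factory({lab: list(rng.normal(1, 0.1, 4))
                               for lab in ["DMSO", "S01", "S02", "S03"]})
        res = anova_gate(wells)
        from scipy.stats import f_oneway
        groups = [g["normalized_translocation"].to_numpy()
                  for _, g in wells.groupby("treatment_label")]
        f, p = f_oneway(*groups)
        assert res.f_stat == pytest.approx(f) and res.p_value == pytest.approx(p)

    def test_null_rejection_rate_near_alpha(self):
        """Under a global null the gate fires at ~5%."""
        rng = np.random.default_rng(123)
        from scipy.stats import f_oneway
        rej = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = rng.normal(0, 1, (8, 4))
            _, p = f_oneway(*groups)
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rej / n_sim - 0.05) < 3 * se

    def test_single_group_is_gate_error(self, wells_factory):
        with pytest.raises(GateError):
            anova_gate(wells_factory({"DMSO": [1.0] * 4}))


class TestDoseResponse:
    def _ladder(self, wells_factory, effects, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        doses = {"DMSO": 0.0}
        groups = {"DMSO": list(1 + rng.normal(0, sd, 4))}
        for d, eff in effects.items():
            lab = f"d{d}"
            doses[lab] = d
            groups[lab] = list(1 + eff + rng.normal(0, sd, 4))
        return wells_factory(groups, doses=doses)

    def test_monotone_ladder_spearman_one(self, wells_factory):
        wells = self._ladder(wells_factory,
                             {1: 0.1, 3: 0.3, 10: 0.6, 30: 0.9, 100: 1.0},
                             sd=0.01, seed=1)
        res = dose_response_summary(wells)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_threshold_is_lowest_planted_active_dose(self, wells_factory):
        """Null doses replicate the vehicle values exactly (zero contrast),
        actives sit far above: the threshold is the lower active dose."""
        rng = np.random.default_rng(2)
        veh = list(1 + rng.normal(0, 0.02, 4))
        groups = {"DMSO": veh, "d1": veh, "d3": veh, "d10": veh,
                  "d30": list(1.8 + rng.normal(0, 0.02, 4)),
                  "d100": list(1.8 + rng.normal(0, 0.02, 4))}
        doses = {"DMSO": 0.0, "d1": 1, "d3": 3, "d10": 10, "d30": 30,
                 "d100": 100}
        res = dose_response_summary(wells_factory(groups, doses=doses))
        assert res.detection_threshold == 30

    def test_flat_null_ladder_reports_none(self, wells_factory):
        wells = self._ladder(wells_factory,
                             {1: 0.0, 3: 0.0, 10: 0.0, 30: 0.0, 100: 0.0},
                             sd=0.02, seed=3)
        res = dose_response_summary(wells)
        assert res.detection_threshold is None

    def test_unreplicated_dose_excluded_with_warning(self, wells_factory):
        wells = self._ladder(wells_factory,
                             {1: 0.0, 3: 0.0, 10: 0.5, 30: 0.5}, sd=0.02,
                             seed=4)
        wells = pd.concat(
            [wells, wells.iloc[[-1]].assign(treatment_label="d100",
                                            dose=100.0, well_id="W999")],
            ignore_index=True)
        with pytest.warns(UserWarning, match="unreplicated"):
            res = dose_response_summary(wells)
        assert "d100" not in set(res.table["treatment_label"])


class TestHeatmap:
    def test_full_plate_geometry(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0] * 4, "S01": [2.0] * 92})
        mat = heatmap_matrix(wells, value="normalized", rows=8, cols=12)
        assert mat.shape == (8, 12)
        assert not mat.isna().any().any()

    def test_empty_well_is_missing_not_zero(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0] * 4})
        mat = heatmap_matrix(wells, value="normalized", rows=8, cols=12)
        assert mat.isna().sum().sum() == 92

    def test_csv_round_trip(self, tmp_path, wells_factory):
        wells = wells_factory({"DMSO": [1.0, 1.5, 0.5, 1.0]})
        mat = heatmap_matrix(wells, value="normalized", rows=8, cols=12)
        p = tmp_path / "m.csv"
        mat.to_csv(p)
        back = pd.read_csv(p, index_col=0)
        back.columns = back.columns.astype(int)
        pd.testing.assert_frame_equal(mat, back)

    def test_duplicate_coordinates_rejected(self, wells_factory):
        wells = wells_factory({"DMSO": [1.0] * 4})
        dup = pd.concat([wells, wells.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValidationError):
            heatmap_matrix(dup, value="normalized")
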