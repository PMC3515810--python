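"""Synthetic-data generator: layouts, fields, ground truth, qPCR tables."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import translocscreen as ts
from translocscreen.errors import CapacityError, PlacementError, ValidationError
from translocscreen.simulate import layout_from_frame, layout_to_frame


class TestPlateLayout:
    def test_counts_for_single_sample_plate(self):
        lay = ts.make_plate_layout(8, 12, 1, 4, seed=1)
        by_class = {c: len(lay.by_class(c)) for c in
                    ("vehicle", "positive_control", "sample")}
        assert by_class == {"vehicle": 4, "positive_control": 4, "sample": 4}
        assert len(lay.wells) == 12  # 84 positions stay empty

    def test_capacity_error_names_requirements(self):
        with pytest.raises(CapacityError, match="284.*96"):
            ts.make_plate_layout(8, 12, 69, 4, seed=0)

    def test_same_seed_reproduces_layout(self):
        a = ts.make_plate_layout(8, 12, 10, 4, seed=7)
        b = ts.make_plate_layout(8, 12, 10, 4, seed=7)
        assert a == b

    def test_balanced_replicates_and_unique_ids(self):
        lay = ts.make_plate_layout(16, 18, 69, 4, seed=3)
        df = layout_to_frame(lay)
        sizes = df.groupby("replicate_group").size()
        assert (sizes == 4).all()
        assert df["well_id"].is_unique

    def test_csv_frame_round_trip(self):
        lay = ts.make_plate_layout(8, 12, 5, 4, seed=2)
        assert layout_from_frame(layout_to_frame(lay), 8, 12) == lay


class TestHillModel:
    def test_zero_dose_gives_f_min(self):
        m = ts.TranslocationModel(f_min=0.2, f_max=0.95)
        assert m.fraction(0.0) == pytest.approx(0.2)

    def test_saturation_approaches_f_max(self):
        m = ts.TranslocationModel(f_min=0.2, f_max=0.95, ec50=10, hill=2)
        assert m.fraction(1e8) == pytest.approx(0.95, abs=1e-6)

    @given(d1=st.floats(0, 1e4), d2=st.floats(0, 1e4),
           hill=st.floats(0.5, 4), ec50=st.floats(0.1, 100))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_dose(self, d1, d2, hill, ec50):
        m = ts.TranslocationModel(f_min=0.1, f_max=0.9, ec50=ec50, hill=hill)
        lo, hi = sorted([d1, d2])
        assert m.fraction(lo) <= m.fraction(hi) + 1e-12


class TestTrueRatio:
    def test_analytic_formula(self):
        # f=0.8 over 100 nuclear px vs 0.2 over 300 cytoplasmic px
        assert ts.true_nc_ratio(0.8, 100, 300) == pytest.approx(12.0)

    def test_equal_partition_equal_areas_is_unity(self):
        assert ts.true_nc_ratio(0.5, 200, 200) == pytest.approx(1.0)


class TestSimulateField:
    def test_ground_truth_fraction_tracks_dose(self, small_acq, noiseless,
                                               sample_entry):
        m = ts.TranslocationModel(f_min=0.2, f_max=0.95, ec50=10, hill=2)
        veh = ts.WellSpec("A01", 0, 0, "DMSO", "vehicle", 0.0, "DMSO")
        _, gt0 = ts.simulate_field(veh, small_acq, ts.CellModel(), m,
                                   noiseless, 5, seed=0)
        assert np.allclose(gt0.cells["true_nuclear_fraction"], 0.2)
        hot = ts.WellSpec("A02", 0, 1, "S01", "sample", 1e7, "S01")
        _, gt1 = ts.simulate_field(hot, small_acq, ts.CellModel(), m,
                                   noiseless, 5, seed=0)
        assert np.allclose(gt1.cells["true_nuclear_fraction"], 0.95,
                           atol=1e-6)

    def test_label_maps_match_truth_areas_and_nesting(self, small_acq,
                                                      noiseless, sample_entry):
        _, gt = ts.simulate_field(sample_entry, small_acq, ts.CellModel(),
                                  ts.TranslocationModel(), noiseless, 12,
                                  seed=4)
        nuc, cell = gt.nucleus_label_map, gt.cell_label_map
        for rec in gt.cells.itertuples():
            n_mask = nuc == rec.cell_id
            c_mask = cell == rec.cell_id
            assert n_mask.sum() == rec.nucleus_area_px
            assert c_mask.sum() == rec.nucleus_area_px + rec.cytoplasm_area_px
            assert (c_mask | ~n_mask).all()  # nucleus inside cell
        # no two cells share a pixel: label maps are single-valued by
        # construction; check cells don't touch-overlap via area sum
        assert (cell > 0).sum() == (gt.cells["nucleus_area_px"]
                                    + gt.cells["cytoplasm_area_px"]).sum()

    def test_gfp_conservation_noise_free(self, small_acq, sample_entry):
        """Summed GFP over a cell equals its total_gfp up to quantization."""
        img, gt = ts.simulate_field(sample_entry, small_acq, ts.CellModel(),
                                    ts.TranslocationModel(),
                                    ts.NoiseModel.noiseless(), 8, seed=2)
        gfp = img.gfp.astype(float)
        for rec in gt.cells.itertuples():
            mask = gt.cell_label_map == rec.cell_id
            total = gfp[mask].sum()
            # rounding each pixel contributes at most 0.5 per pixel
            assert abs(total - rec.total_gfp) <= 0.5 * mask.sum() + 1

    def test_rendered_ratio_matches_analytic_truth(self, small_acq):
        """Noise-free rendered image reproduces (f/A_n)/((1-f)/A_c)."""
        entry = ts.WellSpec("C03", 2, 2, "S01", "sample", 0.0, "S01")
        m = ts.TranslocationModel(f_min=0.8, f_max=0.95)
        img, gt = ts.simulate_field(entry, small_acq, ts.CellModel(),
                                    m, ts.NoiseModel.noiseless(), 6, seed=9)
        gfp = img.gfp.astype(float)
        for rec in gt.cells.itertuples():
            nuc = gt.nucleus_label_map == rec.cell_id
            cyt = (gt.cell_label_map == rec.cell_id) & ~nuc
            measured = gfp[nuc].mean() / gfp[cyt].mean()
            assert measured == pytest.approx(rec.true_nc_ratio, rel=0.02)

    def test_determinism(self, small_acq, noiseless, sample_entry):
        a = ts.simulate_field(sample_entry, small_acq, ts.CellModel(),
                              ts.TranslocationModel(), noiseless, 10, seed=5)
        b = ts.simulate_field(sample_entry, small_acq, ts.CellModel(),
                              ts.TranslocationModel(), noiseless, 10, seed=5)
        assert np.array_equal(a[0].gfp, b[0].gfp)
        assert np.array_equal(a[1].cell_label_map, b[1].cell_label_map)
        pd.testing.assert_frame_equal(a[1].cells, b[1].cells)

    def test_overcrowding_raises_placement_error(self, noiseless):
        acq = ts.AcquisitionSpec(field_width_px=128, field_height_px=128)
        entry = ts.WellSpec("A01", 0, 0, "S01", "sample", 0.0, "S01")
        with pytest.raises(PlacementError):
            ts.simulate_field(entry, acq, ts.CellModel(),ts.TranslocationModel(),
                              noiseless, 200, seed=0,
                              max_attempts_per_cell=20)


class TestSimulatePlate:
    def test_field_count_and_vehicle_fractions(self, noiseless):
        acq = ts.AcquisitionSpec(field_width_px=128, field_height_px=128,
                                 fields_per_well=2)
        lay = ts.make_plate_layout(8, 12, 1, 4, seed=0)
        m = ts.TranslocationModel(f_min=0.3, f_max=0.9)
        out = ts.simulate_plate(lay, acq, ts.CellModel(), m, noiseless,
                                seed=1, n_cells=3)
        assert len(out) == len(lay.wells) * 2
        veh_ids = {w.well_id for w in lay.by_class("vehicle")}
        for wid, _, _, gt in out:
            if wid in veh_ids:
                assert np.allclose(gt.cells["true_nuclear_fraction"], 0.3)

    def test_master_seed_determinism(self, noiseless):
        acq = ts.AcquisitionSpec(field_width_px=128, field_height_px=128,
                                 fields_per_well=1)
        lay = ts.make_plate_layout(8, 12, 1, 4, seed=0)
        kw = dict(n_cells=3)
        a = ts.simulate_plate(lay, acq, ts.CellModel(), ts.TranslocationModel(),
                              noiseless, seed=42, **kw)
        b = ts.simulate_plate(lay, acq, ts.CellModel(), ts.TranslocationModel(),
                              noiseless, seed=42, **kw)
        for (w1, f1, i1, g1), (w2, f2, i2, g2) in zip(a, b):
            assert (w1, f1) == (w2, f2)
            assert np.array_equal(i1.gfp, i2.gfp)
            assert np.array_equal(i1.dna, i2.dna)


class TestSimulateQpcr:
    def test_dilution_spacing_closed_form(self):
        """Perfect doubling: 10-fold steps are log2(10) = 3.3219 cycles."""
        _, dil = ts.simulate_qpcr(["g", "ref"], [("DMSO", 1.0)], "ref",
                                  efficiency=1.0, cq_noise_sd=0.0, seed=0)
        cqs = dil[dil["gene"] == "g"].sort_values("log10_quantity",
                                                  ascending=False)["cq"]
        steps = np.diff(cqs.to_numpy())
        assert steps == pytest.approx(np.log2(10), abs=1e-9)
        assert np.log2(10) == pytest.approx(3.3219, abs=1e-4)

    def test_fold_one_matches_vehicle_cq(self):
        cq, _ = ts.simulate_qpcr(["g", "ref"], [("DMSO", 1.0), ("X", 1.0)],
                                 "ref", cq_noise_sd=0.0, seed=0)
        g = cq[cq["gene"] == "g"].groupby("condition")["cq"].mean()
        assert g["X"] == pytest.approx(g["DMSO"], abs=1e-12)

    def test_fold_eight_shifts_three_cycles(self):
        cq, _ = ts.simulate_qpcr(["g", "ref"], [("DMSO", 1.0), ("X", 8.0)],
                                 "ref", efficiency=1.0, cq_noise_sd=0.0, seed=0)
        g = cq[cq["gene"] == "g"].groupby("condition")["cq"].mean()
        assert g["X"] - g["DMSO"] == pytest.approx(-3.0, abs=1e-9)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValidationError):
            ts.simulate_qpcr(["g", "ref"], [("DMSO", 1.0), ("X", 0.0)], "ref")

    def test_reference_gene_flat_across_conditions(self):
        cq, _ = ts.simulate_qpcr(["g", "ref"], [("DMSO", 1.0), ("X", 5.0)],
                                 "ref", cq_noise_sd=0.0, seed=0)
        r = cq[cq["gene"] == "ref"].groupby("condition")["cq"].mean()
        assert r["X"] == pytest.approx(r["DMSO"], abs=1e-12)
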