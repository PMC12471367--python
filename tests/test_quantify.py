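"""LPD-equivalent quantification: linearity, hand arithmetic, LoD and
generator round-trips."""


import pytest

from amphiscan import LpdStandard, cell_quota, concentration, lod, quantify_panel
from amphiscan.spectra_io import CountTables, PeakAreaRecord, ValidationError
from amphiscan.synthetic_data import PanelConfig, make_panel

STD = LpdStandard(conc_ng_per_ul=13.0, peak_area=2.0e5, snr=39.0)


class TestConcentration:
    def test_identity_ratio(self):
        assert concentration(STD.peak_area, STD) == pytest.approx(13.0)

    def test_zero_area_zero_concentration(self):
        assert concentration(0.0, STD) == 0.0

    def test_linearity(self):
        assert concentration(2 * STD.peak_area, STD) == pytest.approx(26.0)
        for k in (0.5, 3.0, 10.0):
            assert concentration(k * STD.peak_area, STD) == pytest.approx(13.0 * k)

    def test_zero_standard_area_rejected(self):
        with pytest.raises(ValidationError):
            LpdStandard(13.0, 0.0, 39.0)


class TestCellQuota:
    def test_unit_conversion(self):
        # 1 ng/uL in 500 uL over 1e6 cells = 500 fg/cell
        assert cell_quota(1.0, 500.0, 1_000_000) == pytest.approx(500.0)

    def test_zero_concentration(self):
        assert cell_quota(0.0, 500.0, 1_000_000) == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValidationError):
            cell_quota(1.0, 500.0, 0)


class TestLod:
    def test_hand_arithmetic(self):
        # 13 * 3/39 = 1 ng/uL; x 500 uL x 1e6 / 1e6 cells = 500 fg/cell
        assert lod(STD, 500.0, 1_000_000) == pytest.approx(500.0)

    def test_snr_three_equals_standard_quota(self):
        std3 = LpdStandard(13.0, 1.0, 3.0)
        assert lod(std3, 500.0, 1_000_000) == pytest.approx(
            cell_quota(13.0, 500.0, 1_000_000)
        )

    def test_inverse_proportional_to_cells(self):
        assert lod(STD, 500.0, 2_000_000) == pytest.approx(
            lod(STD, 500.0, 1_000_000) / 2
        )

    def test_zero_snr_rejected(self):
        with pytest.raises(ValidationError):
            lod(LpdStandard(13.0, 1.0, 0.0), 500.0, 1_000_000)


class TestQuantifyPanel:
    def test_noise_free_panel_recovers_planted_quotas_exactly(self):
        cfg = PanelConfig(n_strains=9, area_cv=0.0, seed=3)
        panel = make_panel(cfg)
        std = LpdStandard(
            panel.truth["std_conc_ng_per_ul"], panel.truth["std_peak_area"], 30.0
        )
        records, totals = quantify_panel(panel.peak_areas, std, panel.counts)
        assert records
        for rec in records:
            truth = panel.truth["quotas_fg_per_cell"][rec.strain_id][rec.variant_name]
            assert rec.cell_quota_fg_per_cell == pytest.approx(truth, rel=1e-12)
        # totals equal the sum of above-LoD planted quotas
        for strain in panel.counts.cell_counts:
            above = [
                r.cell_quota_fg_per_cell
                for r in records
                if r.strain_id == strain and not r.below_lod
            ]
            assert totals[strain] == pytest.approx(sum(above), rel=1e-12)

    def test_noisy_panel_recovers_quotas_within_generator_cv(self):
        cfg = PanelConfig(n_strains=30, area_cv=0.2, seed=11)
        panel = make_panel(cfg)
        std = LpdStandard(
            panel.truth["std_conc_ng_per_ul"], panel.truth["std_peak_area"], 30.0
        )
        records, _ = quantify_panel(panel.peak_areas, std, panel.counts)
        rel_errors = [
            abs(r.cell_quota_fg_per_cell
                - panel.truth["quotas_fg_per_cell"][r.strain_id][r.variant_name])
            / panel.truth["quotas_fg_per_cell"][r.strain_id][r.variant_name]
            for r in records
        ]
        # lognormal CV 0.2: individual errors bounded by a few CVs
        assert max(rel_errors) < 5 * 0.2
        assert sum(rel_errors) / len(rel_errors) < 2 * 0.2

    def test_strain_without_hits_reports_total_zero(self):
        counts = CountTables(
            cell_counts={"S1": (1_000_000, 500.0)}, assay_counts={}
        )
        records, totals = quantify_panel([], STD, counts)
        assert records == []
        assert totals == {"S1": 0.0}

    def test_below_lod_variant_flagged_and_excluded_from_total(self):
        counts = CountTables(cell_counts={"S1": (1_000_000, 500.0)}, assay_counts={})
        # LoD with STD = 500 fg/cell; plant one variant far below it
        tiny = PeakAreaRecord("S1", "AM-X", peak_area=1.0)
        big = PeakAreaRecord("S1", "AM-Y", peak_area=1.0e6)
        records, totals = quantify_panel([tiny, big], STD, counts)
        by_name = {r.variant_name: r for r in records}
        assert by_name["AM-X"].below_lod
        assert not by_name["AM-Y"].below_lod
        assert totals["S1"] == pytest.approx(by_name["AM-Y"].cell_quota_fg_per_cell)

    def test_missing_cell_counts_skips_strain_with_warning(self, caplog):
        import logging

        logging.getLogger("amphiscan").setLevel(logging.WARNING)
        counts = CountTables(cell_counts={}, assay_counts={})
        with caplog.at_level("WARNING", logger="amphiscan.quantify"):
            records, _ = quantify_panel(
                [PeakAreaRecord("S9", "AM-X", 100.0)], STD, counts
            )
        assert records == []
        assert any("no cell counts" in r.message for r in caplog.records)

    def test_quota_linear_in_area(self):
        counts = CountTables(cell_counts={"S1": (2_000_000, 500.0)}, assay_counts={})
        base, _ = quantify_panel([PeakAreaRecord("S1", "V", 1.0e5)], STD, counts)
        scaled, _ = quantify_panel([PeakAreaRecord("S1", "V", 3.0e5)], STD, counts)
        assert scaled[0].cell_quota_fg_per_cell == pytest.approx(
            3 * base[0].cell_quota_fg_per_cell
        )
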