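"""Carbon partition, nutrient reallocation and the four-term CDR budget."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seaweed_cdr.budget import (
    BiomassRecord,
    StoichiometryParams,
    budget_from_wet_weight,
    calcification_offset,
    cdr_theoretical,
    doc_production,
    nutrient_uptake,
    organic_cn_ratio,
    organic_cp_ratio,
    partition_carbon,
    plankton_displacement,
    propagate_bounds,
    read_biomass_csv,
    reallocation_discount,
    to_gigatonnes_co2,
    wet_weight_to_tpc,
    write_biomass_csv,
)
from seaweed_cdr.carbonate import DomainError

PEAK_WW = 18.8  # Mt wet weight of the 2018 bloom
PSI = 0.63


class TestPartition:
    def test_tpc_conversion(self):
        assert wet_weight_to_tpc(PEAK_WW) == pytest.approx(1.02, abs=0.005)
        assert wet_weight_to_tpc(0.0) == 0.0
        assert wet_weight_to_tpc(100.0) == pytest.approx(5.43)
        with pytest.raises(DomainError):
            wet_weight_to_tpc(-1.0)

    def test_mass_conservation(self):
        p = partition_carbon(PEAK_WW)
        assert p.pic_mol + p.poc_mol == pytest.approx(p.tpc_mol)
        assert p.pic_mt + p.poc_mt == pytest.approx(p.tpc_mt)
        assert p.pic_poc_ratio == pytest.approx(p.pic_mol / p.poc_mol)

    @pytest.mark.parametrize("fraction,expected_ratio", [
        (0.043, 0.11), (0.214, 0.9),
    ])
    def test_reported_ratio_endpoints(self, fraction, expected_ratio):
        p = partition_carbon(
            PEAK_WW, StoichiometryParams(caco3_ww_fraction=fraction))
        assert p.pic_poc_ratio == pytest.approx(expected_ratio, abs=0.01)

    def test_zero_fraction_gives_pure_poc(self):
        params = StoichiometryParams(caco3_ww_fraction=1e-12)
        p = partition_carbon(PEAK_WW, params)
        assert p.pic_mol == pytest.approx(0.0, abs=1.0)
        assert p.poc_mt == pytest.approx(p.tpc_mt)

    def test_infeasible_fraction_rejected(self):
        # a CaCO3 fraction this large implies PIC > TPC
        with pytest.raises(DomainError, match="infeasible"):
            partition_carbon(PEAK_WW,
                             StoichiometryParams(caco3_ww_fraction=0.6))


class TestCalcificationOffset:
    def test_central_value(self):
        p = partition_carbon(PEAK_WW)
        assert calcification_offset(p, PSI) == pytest.approx(0.165, abs=0.002)

    def test_upper_end(self):
        p = partition_carbon(
            PEAK_WW, StoichiometryParams(caco3_ww_fraction=0.214))
        assert calcification_offset(p, PSI) == pytest.approx(0.57, abs=0.01)

    def test_no_pic_no_offset(self):
        p = partition_carbon(PEAK_WW,
                             StoichiometryParams(caco3_ww_fraction=1e-12))
        assert calcification_offset(p, PSI) == pytest.approx(0.0, abs=1e-10)

    def test_psi_validated(self):
        with pytest.raises(DomainError):
            calcification_offset(partition_carbon(PEAK_WW), 1.5)


class TestNutrients:
    def test_bloom_inventories(self):
        nu = nutrient_uptake(PEAK_WW)
        assert nu["N"] == pytest.approx(2.7, abs=0.05)
        assert nu["P"] == pytest.approx(0.12, abs=0.005)
        assert nu["Fe"] == pytest.approx(0.003, abs=0.0005)

    def test_zero_biomass(self):
        assert all(v == 0.0 for v in nutrient_uptake(0.0).values())

    def test_organic_ratios_after_pic_correction(self):
        p = partition_carbon(PEAK_WW)
        assert organic_cn_ratio(p, PEAK_WW) == pytest.approx(24.8, abs=0.5)
        assert organic_cp_ratio(p, PEAK_WW) == pytest.approx(550.0, rel=0.02)

    def test_plankton_fixation_from_reallocated_nitrogen(self):
        disp = plankton_displacement({"N": 2.7}, "N",
                                     StoichiometryParams(), PSI)
        assert disp["poc_plankton"] == pytest.approx(0.26, abs=0.005)

    def test_no_plankton_calcification_no_credit(self):
        params = StoichiometryParams(plankton_pic_poc=0.0)
        disp = plankton_displacement({"N": 2.7}, "N", params, PSI)
        assert disp["pic_plankton_co2"] == 0.0

    def test_unknown_limiting_nutrient_rejected(self):
        with pytest.raises(ValueError, match="limiting"):
            plankton_displacement({"N": 2.7}, "Fe", StoichiometryParams(), PSI)

    def test_reallocation_discount_values(self):
        assert reallocation_discount(24.8, 8.0) == pytest.approx(0.32, abs=0.005)
        assert reallocation_discount(8.0, 8.0) == 1.0
        assert reallocation_discount(16.0, 8.0) == 0.5
        with pytest.raises(DomainError):
            reallocation_discount(0.0, 8.0)

    def test_n_and_p_limitation_agree_within_two_points(self):
        """N- vs P-limitation change the discount by < 2 percentage points."""
        p = partition_carbon(PEAK_WW)
        n_disc = reallocation_discount(organic_cn_ratio(p, PEAK_WW), 8.0)
        p_disc = reallocation_discount(organic_cp_ratio(p, PEAK_WW), 170.0)
        assert abs(n_disc - p_disc) < 0.02


class TestBudget:
    def test_bloom_budget_terms(self, ref_state):
        b = budget_from_wet_weight(PEAK_WW, ref_state.psi)
        assert b.poc_seaweed == pytest.approx(0.81, abs=0.005)
        assert b.pic_seaweed_co2 == pytest.approx(0.13, abs=0.005)
        assert b.poc_plankton == pytest.approx(0.26, abs=0.005)
        assert b.pic_plankton_co2 == pytest.approx(0.002, abs=0.0005)
        assert b.cdr_theoretical == pytest.approx(0.42, abs=0.005)

    def test_budget_identity(self, ref_state):
        b = budget_from_wet_weight(PEAK_WW, ref_state.psi)
        assert b.cdr_theoretical == pytest.approx(
            b.poc_seaweed - b.pic_seaweed_co2
            - b.poc_plankton + b.pic_plankton_co2)

    def test_zero_biomass_zero_budget(self):
        b = budget_from_wet_weight(0.0, PSI)
        assert b.cdr_theoretical == 0.0 and b.poc_seaweed == 0.0

    def test_psi_zero_switches_off_calcification_terms(self):
        partition = partition_carbon(PEAK_WW)
        disp = plankton_displacement(nutrient_uptake(PEAK_WW), "N",
                                     StoichiometryParams(), 0.0)
        b = cdr_theoretical(partition, disp, 0.0)
        assert b.pic_seaweed_co2 == 0.0 and b.pic_plankton_co2 == 0.0
        assert b.cdr_theoretical == pytest.approx(
            b.poc_seaweed - b.poc_plankton)

    def test_net_decreases_with_caco3_and_increases_with_cn(self):
        nets_f = [
            budget_from_wet_weight(
                PEAK_WW, PSI,
                StoichiometryParams(caco3_ww_fraction=f)).cdr_theoretical
            for f in (0.043, 0.094, 0.214)
        ]
        assert nets_f == sorted(nets_f, reverse=True)
        # higher seaweed C:N = less N per unit POC = smaller plankton offset
        params = StoichiometryParams()
        partition = partition_carbon(PEAK_WW, params)
        nets_cn = []
        for cn in (16.0, 24.8, 108.0):
            n_gmol = partition.poc_mol / cn / 1e9
            disp = plankton_displacement({"N": n_gmol}, "N", params, PSI)
            nets_cn.append(cdr_theoretical(partition, disp, PSI).cdr_theoretical)
        assert nets_cn == sorted(nets_cn)


class TestBounds:
    def test_worked_bound_endpoints(self, ref_state):
        p = partition_carbon(PEAK_WW)
        bounds = propagate_bounds(StoichiometryParams(), p.tpc_mol,
                                  ref_state.psi)
        # the printed "~ -3" and "~ 77" come from integer-rounded
        # intermediates; the continuous evaluation lands within half a mol
        assert bounds["lower"]["net"] == pytest.approx(-3.0, abs=0.5)
        assert bounds["upper"]["net"] == pytest.approx(77.0, abs=1.0)
        assert bounds["lower"]["mt_c"] == pytest.approx(-0.03, abs=0.005)
        assert bounds["upper"]["mt_c"] == pytest.approx(0.79, abs=0.01)

    def test_degenerate_ranges_collapse_to_central(self, ref_state):
        p = partition_carbon(PEAK_WW)
        cn = organic_cn_ratio(p, PEAK_WW)
        params = StoichiometryParams(caco3_ww_range=(0.094, 0.094),
                                     seaweed_cn_range=(cn, cn))
        bounds = propagate_bounds(params, p.tpc_mol, ref_state.psi)
        central = budget_from_wet_weight(PEAK_WW, ref_state.psi).cdr_theoretical
        assert bounds["lower"]["mt_c"] == pytest.approx(bounds["upper"]["mt_c"])
        assert bounds["lower"]["mt_c"] == pytest.approx(central, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(f_lo=st.floats(0.043, 0.094), f_hi=st.floats(0.094, 0.214),
           cn_lo=st.floats(16.0, 24.8), cn_hi=st.floats(24.8, 108.0))
    def test_bound_ordering(self, f_lo, f_hi, cn_lo, cn_hi):
        params = StoichiometryParams(caco3_ww_range=(f_lo, f_hi),
                                     seaweed_cn_range=(cn_lo, cn_hi))
        p = partition_carbon(PEAK_WW)
        bounds = propagate_bounds(params, p.tpc_mol, PSI)
        assert bounds["lower"]["net"] <= bounds["upper"]["net"]

    def test_net_changes_sign_within_admissible_fractions(self):
        """At C:N 16 the 100-mol net crosses zero inside [0.043, 0.214]."""
        p = partition_carbon(PEAK_WW)
        nets = {}
        for f in (0.043, 0.214):
            params = StoichiometryParams(caco3_ww_range=(f, f),
                                         seaweed_cn_range=(16.0, 16.0))
            nets[f] = propagate_bounds(params, p.tpc_mol, PSI)["lower"]["net"]
        assert nets[0.043] > 0.0 > nets[0.214]


class TestDocAndUnits:
    def test_single_month_arithmetic(self):
        series = [BiomassRecord(month="2018-04", wet_weight=1.0)]  # 30 days
        assert doc_production(series) == pytest.approx(0.00864, rel=1e-12)

    def test_zero_series(self):
        series = [BiomassRecord(month="2018-01", wet_weight=0.0),
                  BiomassRecord(month="2018-02", wet_weight=0.0)]
        assert doc_production(series) == 0.0

    def test_bloom_scale_series_produces_order_one_megatonne(self, bloom_series):
        assert 0.5 < doc_production(bloom_series) < 2.0

    def test_unordered_series_rejected(self):
        series = [BiomassRecord(month="2018-02", wet_weight=1.0),
                  BiomassRecord(month="2018-01", wet_weight=1.0)]
        with pytest.raises(ValueError, match="chronological"):
            doc_production(series)

    def test_mtc_to_gtco2(self):
        assert to_gigatonnes_co2(0.79) == pytest.approx(0.0029, abs=0.0001)
        assert to_gigatonnes_co2(-0.03) == pytest.approx(-0.00011, abs=0.00002)
        assert to_gigatonnes_co2(0.0) == 0.0

    def test_csv_round_trip(self, tmp_path, bloom_series):
        path = tmp_path / "series.csv"
        write_biomass_csv(bloom_series, path)
        back = read_biomass_csv(path)
        assert [r.month for r in back] == [r.month for r in bloom_series]
        for a, b in zip(back, bloom_series):
            assert a.wet_weight == pytest.approx(b.wet_weight, rel=1e-12)
            assert a.coverage == pytest.approx(b.coverage, rel=1e-12)

    def test_csv_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("month,biomass\n2018-01,1.0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_biomass_csv(path)
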