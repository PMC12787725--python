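"""Daily-intake, hazard-quotient and carcinogenic-risk arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddyrisk import (
    Metal,
    adi_food,
    adi_soil,
    aggregate_risk,
    carcinogenic_risk,
    classify_risk,
    compute_risk_table,
    hazard_quotient,
)
from paddyrisk import defaults
from paddyrisk.core_data import ExposureParameterSet, Pathway


@pytest.fixture
def adult():
    # IR 0.3 kg/d, IngR 100 mg/d, EF 350 d/y, ED 24 y, BW 60 kg, AT 8760 d
    return defaults.EXPOSURE_ADULT


class TestDailyIntake:
    def test_food_pathway_hand_arithmetic(self, adult):
        # 0.5 * 0.3 * 350 * 24 / (60 * 8760)
        assert adi_food(0.5, adult, "nc") == pytest.approx(2.3973e-3, rel=1e-4)

    def test_zero_concentration_gives_zero(self, adult):
        assert adi_food(0.0, adult) == 0.0
        for p in (Pathway.ING, Pathway.INH, Pathway.DER):
            assert adi_soil(0.0, adult, p) == 0.0

    def test_doubling_body_weight_halves_intake(self, adult):
        heavy = ExposureParameterSet(**{**adult.model_dump(), "BW": 2 * adult.BW})
        assert adi_food(0.5, heavy) == pytest.approx(adi_food(0.5, adult) / 2)

    def test_soil_ingestion_hand_arithmetic(self, adult):
        # 652.34 * 100 * 350 * 24 / (60 * 8760) * 1e-6
        assert adi_soil(652.34, adult, Pathway.ING, "nc") == pytest.approx(1.0425e-3, rel=1e-4)

    def test_inhalation_is_ingestion_scaled_by_rates_and_pef(self, adult):
        ing = adi_soil(100.0, adult, Pathway.ING)
        inh = adi_soil(100.0, adult, Pathway.INH)
        assert inh == pytest.approx(ing * (adult.InhR / adult.IngR) / adult.PEF)

    def test_food_pathway_refused_by_adi_soil(self, adult):
        with pytest.raises(ValueError, match="adi_food"):
            adi_soil(1.0, adult, Pathway.FOOD)

    def test_carcinogenic_averaging_uses_lifetime(self, adult):
        nc = adi_food(0.5, adult, "nc")
        ca = adi_food(0.5, adult, "ca")
        assert ca == pytest.approx(nc * adult.AT_nc / adult.AT_ca)


class TestQuotients:
    @pytest.mark.parametrize("adi, rfd, expected", [
        (1e-3, 1e-3, 1.0),
        (0.0, 0.5, 0.0),
        (2e-3, 1e-3, 2.0),
    ])
    def test_hazard_quotient(self, adi, rfd, expected):
        assert hazard_quotient(adi, rfd) == expected

    def test_hazard_quotient_requires_positive_rfd(self):
        with pytest.raises(ValueError):
            hazard_quotient(1.0, 0.0)

    def test_carcinogenic_risk(self):
        assert carcinogenic_risk(1e-3, 1.5) == pytest.approx(1.5e-3)
        assert carcinogenic_risk(1e-3, None) is None  # no slope factor -> no cell
        assert carcinogenic_risk(0.0, 2.0) == 0.0


class TestAggregateRisk:
    def test_published_margins_reproduced(self, printed_cells):
        table = aggregate_risk(printed_cells)
        assert table.hi("adult") == pytest.approx(49.41, abs=0.01)
        assert table.hi("child") == pytest.approx(104.83, abs=0.02)
        assert table.pathway_totals("adult", "hq")[Pathway.FOOD] == pytest.approx(48.95, abs=0.005)
        assert table.pathway_totals("child", "hq")[Pathway.ING] == pytest.approx(1.39, abs=0.005)
        assert table.tcr("adult") == pytest.approx(4.23e-2, rel=2e-3)
        assert table.tcr("child") == pytest.approx(8.92e-2, rel=2e-3)

    def test_metals_without_slope_factor_have_no_cr_total(self, printed_cells):
        table = aggregate_risk(printed_cells)
        mt = table.metal_totals.set_index(["population", "metal"])
        assert np.isnan(mt.loc[("adult", Metal.CU), "cr_total"])
        assert np.isnan(mt.loc[("child", Metal.ZN), "cr_total"])
        # Pb has a CR total despite its absent dermal cell
        assert mt.loc[("adult", Metal.PB), "cr_total"] == pytest.approx(1.62e-4, rel=5e-3)

    def test_all_zero_cells_give_zero_totals(self):
        cells = pd.DataFrame(
            dict(population=["adult"] * 4, metal=["Cd"] * 4,
                 pathway=["food", "ing", "inh", "der"], hq=[0.0] * 4, cr=[0.0] * 4)
        )
        table = aggregate_risk(cells)
        assert table.hi("adult") == 0.0
        assert table.tcr("adult") == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_hi_independent_of_summation_grouping(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for m in ("Cu", "Cd", "Pb"):
            for p in ("food", "ing", "inh", "der"):
                rows.append(dict(population="adult", metal=m, pathway=p,
                                 hq=float(rng.uniform(0, 10)), cr=None))
        cells = pd.DataFrame(rows)
        table = aggregate_risk(cells)
        # pathway-then-metal vs metal-then-pathway
        by_pathway = sum(table.pathway_totals("adult", "hq").values())
        assert table.hi("adult") == pytest.approx(by_pathway, rel=1e-12)


class TestComputeRiskTable:
    def test_scaling_concentrations_by_power_of_two_scales_hi_tcr_exactly(self):
        c_rice = {m: 0.1 * (i + 1) for i, m in enumerate(Metal)}
        c_soil = dict(defaults.SOIL_MEANS_CONTAMINATED)
        base = compute_risk_table(c_rice, c_soil, defaults.EXPOSURE_DEFAULTS,
                                  defaults.TOXREF_DEFAULT)
        k = 2.0
        scaled = compute_risk_table({m: k * v for m, v in c_rice.items()},
                                    {m: k * v for m, v in c_soil.items()},
                                    defaults.EXPOSURE_DEFAULTS, defaults.TOXREF_DEFAULT)
        for pop in ("adult", "child"):
            assert scaled.hi(pop) == k * base.hi(pop)
            assert scaled.tcr(pop) == k * base.tcr(pop)

    def test_structure_matches_published_layout(self):
        c = {m: 1.0 for m in Metal}
        table = compute_risk_table(c, c, defaults.EXPOSURE_DEFAULTS, defaults.TOXREF_DEFAULT)
        cells = table.cells.set_index(["population", "metal", "pathway"])
        assert np.isnan(cells.loc[("adult", Metal.PB, Pathway.DER), "cr"])
        for m in (Metal.CU, Metal.ZN):
            assert cells.loc[("adult", m)]["cr"].isna().all()
        frame = table.table3_frame()
        assert list(frame.columns) == [
            "metal", "population",
            "HQ_food", "HQ_ing", "HQ_inh", "HQ_der", "HQ_total",
            "CR_food", "CR_ing", "CR_inh", "CR_der", "CR_total",
        ]
        assert (frame[frame["metal"] == "Cu"]["CR_total"] == "—").all()


class TestClassifyRisk:
    @pytest.mark.parametrize("value, kind, label", [
        (49.41, "HQ_HI", "risk"),
        (1.0, "HQ_HI", "no potential risk"),   # strict threshold
        (5e-5, "CR_TCR", "acceptable"),
        (4.23e-2, "CR_TCR", "unacceptable"),
        (1e-7, "CR_TCR", "no obvious risk"),
    ])
    def test_labels(self, value, kind, label):
        assert classify_risk(value, kind) == label
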