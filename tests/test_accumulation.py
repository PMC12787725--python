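"""Bioconcentration/translocation factors: ratios, aggregation, rankings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddyrisk import (
    FactorKind,
    Group,
    Metal,
    Stage,
    Tissue,
    compute_ratio,
    generate,
    rank_metals,
    transfer_table,
)
from paddyrisk.accumulation import TransferFactorTable
from paddyrisk.core_data import DataValidationError
from paddyrisk.synthetic import GeneratorConfig
import pandas as pd


class TestComputeRatio:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (3.9195, 2.01, 1.95),  # root Cd at maturity over soil Cd
            (5.0, 5.0, 1.0),
            (0.0, 2.0, 0.0),
        ],
    )
    def test_examples(self, num, den, expected):
        assert compute_ratio(num, den) == pytest.approx(expected)

    def test_zero_denominator_is_domain_error(self):
        with pytest.raises(ValueError, match="denominator"):
            compute_ratio(1.0, 0.0)


def _factor_table(values):
    """Build a TransferFactorTable directly from {(metal, stage, kind): value}."""
    rows = [
        dict(metal=m, stage=s, kind=k, value=v, sd=np.nan, n=1, absent_reason=None)
        for (m, s, k), v in values.items()
    ]
    return TransferFactorTable(pd.DataFrame(rows))


class TestTransferTable:
    def test_noise_free_generator_recovers_true_factors_exactly(self):
        ds = generate(GeneratorConfig(seed=7, soil_cv=0.0, tissue_noise_sd=0.0))
        table = transfer_table(
            ds.tissue.subset(group=Group.CONTAMINATED),
            ds.soil.subset(group=Group.CONTAMINATED),
        )
        assert table.value(Metal.CD, Stage.MATURITY, FactorKind.BF_ROOT_SOIL) == pytest.approx(1.95)
        assert table.value(Metal.PB, Stage.TILLERING, FactorKind.TF_STEM_ROOT) == pytest.approx(0.04)

    def test_grain_factors_absent_at_tillering(self):
        ds = generate(GeneratorConfig(seed=7))
        table = transfer_table(
            ds.tissue.subset(group=Group.CONTAMINATED),
            ds.soil.subset(group=Group.CONTAMINATED),
        )
        for m in Metal:
            assert table.value(m, Stage.TILLERING, FactorKind.TF_GRAIN_STEM) is None
            assert table.value(m, Stage.MATURITY, FactorKind.TF_GRAIN_STEM) is not None
        df = table.data
        absent = df[(df["stage"] == Stage.TILLERING) & (df["kind"] == FactorKind.TF_GRAIN_STEM)]
        assert (absent["absent_reason"].notna()).all()

    def test_noisy_estimate_within_three_se_of_truth(self):
        # sampling-theory bound: ratio noise is unit-mean lognormal sigma=0.1,
        # so the 4-replicate mean has SE ~= truth * 0.1 / 2
        truth = 1.95
        ds = generate(GeneratorConfig(seed=11, tissue_noise_sd=0.1, n_replicates=4))
        table = transfer_table(
            ds.tissue.subset(group=Group.CONTAMINATED),
            ds.soil.subset(group=Group.CONTAMINATED),
        )
        est = table.value(Metal.CD, Stage.MATURITY, FactorKind.BF_ROOT_SOIL)
        se = truth * 0.1 / np.sqrt(4)
        assert abs(est - truth) < 3 * se

    @given(k=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_scale_invariance(self, k):
        ds = generate(GeneratorConfig(seed=3, n_replicates=2))
        soil = ds.soil.subset(group=Group.CONTAMINATED)
        tissue = ds.tissue.subset(group=Group.CONTAMINATED)
        base = transfer_table(tissue, soil)
        scaled_soil = type(soil)(soil.data.assign(concentration=soil.data.concentration * k), kind="soil")
        scaled_tissue = type(tissue)(tissue.data.assign(concentration=tissue.data.concentration * k), kind="tissue")
        scaled = transfer_table(scaled_tissue, scaled_soil)
        np.testing.assert_allclose(
            scaled.data["value"].to_numpy(dtype=float),
            base.data["value"].to_numpy(dtype=float),
            rtol=1e-9, equal_nan=True,
        )

    def test_chain_consistency_noise_free(self):
        ds = generate(GeneratorConfig(seed=5, soil_cv=0.0, tissue_noise_sd=0.0))
        soil = ds.soil.subset(group=Group.CONTAMINATED)
        tissue = ds.tissue.subset(group=Group.CONTAMINATED)
        table = transfer_table(tissue, soil)
        for m in Metal:
            bf = table.value(m, Stage.HEADING, FactorKind.BF_ROOT_SOIL)
            tsr = table.value(m, Stage.HEADING, FactorKind.TF_STEM_ROOT)
            tls = table.value(m, Stage.HEADING, FactorKind.TF_LEAF_STEM)
            c_soil = soil.mean_by_metal()[m]
            c_leaf = tissue.subset(stage=Stage.HEADING, tissue=Tissue.LEAF).mean_by_metal()[m]
            assert bf * tsr * tls == pytest.approx(c_leaf / c_soil, rel=1e-12)


class TestRankMetals:
    def test_maturity_bioconcentration_ordering(self):
        values = {
            (Metal.CU, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 0.60,
            (Metal.CR, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 0.35,
            (Metal.ZN, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 0.52,
            (Metal.CD, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 1.95,
            (Metal.PB, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 0.75,
            (Metal.AS, Stage.MATURITY, FactorKind.BF_ROOT_SOIL): 0.32,
        }
        order, ties = rank_metals(_factor_table(values), FactorKind.BF_ROOT_SOIL, Stage.MATURITY)
        assert [m.value for m in order] == ["Cd", "Pb", "Cu", "Zn", "Cr", "As"]
        assert not ties

    def test_heading_stem_root_ordering(self):
        values = {
            (Metal.CU, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.28,
            (Metal.CR, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.52,
            (Metal.ZN, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.43,
            (Metal.CD, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.35,
            (Metal.PB, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.06,
            (Metal.AS, Stage.HEADING, FactorKind.TF_STEM_ROOT): 0.36,
        }
        order, _ = rank_metals(_factor_table(values), FactorKind.TF_STEM_ROOT, Stage.HEADING)
        assert [m.value for m in order] == ["Cr", "Zn", "As", "Cd", "Cu", "Pb"]

    def test_all_equal_uses_canonical_order_and_flags_ties(self):
        values = {
            (m, Stage.TILLERING, FactorKind.BF_ROOT_SOIL): 0.5 for m in Metal
        }
        order, ties = rank_metals(_factor_table(values), FactorKind.BF_ROOT_SOIL, Stage.TILLERING)
        assert order == list(Metal)
        assert ties

    def test_missing_metal_raises_naming_it(self):
        values = {
            (m, Stage.TILLERING, FactorKind.BF_ROOT_SOIL): 0.5
            for m in Metal if m != Metal.ZN
        }
        with pytest.raises(DataValidationError, match="Zn"):
            rank_metals(_factor_table(values), FactorKind.BF_ROOT_SOIL, Stage.TILLERING)
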