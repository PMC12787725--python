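"""Distribution sampling and uncertainty propagation."""

import numpy as np
import pytest
from scipy import stats

from paddyrisk import DistributionSpec, Metal, compute_risk_table, sample, simulate
from paddyrisk import defaults
from paddyrisk.core_data import METAL_ORDER


@pytest.fixture
def fixed_inputs():
    c_rice = {m: 0.2 for m in Metal}
    c_soil = dict(defaults.SOIL_MEANS_CONTAMINATED)
    return c_rice, c_soil, defaults.EXPOSURE_DEFAULTS, defaults.TOXREF_DEFAULT


class TestSample:
    def test_point_distribution(self):
        np.testing.assert_array_equal(sample(DistributionSpec.point(3.0), 5, 0),
                                      np.full(5, 3.0))

    def test_uniform_mean_close_to_half(self):
        draws = sample(DistributionSpec(family="uniform", low=0, high=1), 10_000, 42)
        assert abs(draws.mean() - 0.5) < 0.02  # CLT bound ~3*sd/sqrt(n)

    def test_truncated_normal_respects_bounds(self):
        spec = DistributionSpec.normal(0.0, 1.0, lower=0.0)
        draws = sample(spec, 5000, 1)
        assert (draws >= 0).all()
        assert len(draws) == 5000

    def test_seed_reproducibility(self):
        spec = DistributionSpec.lognormal_from_mean_cv(10.0, 0.3)
        a = sample(spec, 1000, 7)
        b = sample(spec, 1000, 7)
        np.testing.assert_array_equal(a, b)

    def test_impossible_truncation_rejected(self):
        spec = DistributionSpec.normal(0.0, 1.0, lower=50.0)
        with pytest.raises(ValueError, match="exclude"):
            sample(spec, 100, 0)

    def test_lognormal_moment_matching(self):
        spec = DistributionSpec.lognormal_from_mean_cv(652.34, 29.73 / 652.34)
        draws = sample(spec, 100_000, 9)
        assert draws.mean() == pytest.approx(652.34, rel=0.005)
        assert draws.std(ddof=1) == pytest.approx(29.73, rel=0.05)

    def test_invalid_family_and_params_rejected(self):
        with pytest.raises(ValueError, match="family"):
            DistributionSpec(family="beta", low=0, high=1)
        with pytest.raises(ValueError, match="sd"):
            DistributionSpec(family="normal", mean=0, sd=-1)


class TestSimulate:
    def test_point_distributions_reproduce_deterministic_pipeline_bitwise(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        det = compute_risk_table(c_rice, c_soil, exposures, toxref)
        dists = {f"c_soil.{m.value}": DistributionSpec.point(c_soil[m]) for m in c_soil}
        dists.update({f"c_rice.{m.value}": DistributionSpec.point(c_rice[m]) for m in c_rice})
        res = simulate(c_rice, c_soil, exposures, toxref, dists, n=64, seed=5,
                       keep_draws=True)
        mt = det.metal_totals.set_index(["population", "metal"])
        for pop in ("adult", "child"):
            assert (res.draws[f"{pop}.HI"] == det.hi(pop)).all()
            assert (res.draws[f"{pop}.TCR"] == det.tcr(pop)).all()
            for m in METAL_ORDER:
                assert (res.draws[f"{pop}.HQ_{m.value}"] == mt.loc[(pop, m), "hq_total"]).all()

    def test_degenerate_exceedance_is_zero_or_one(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        det = compute_risk_table(c_rice, c_soil, exposures, toxref)
        assert det.hi("adult") > 1
        res = simulate(c_rice, c_soil, exposures, toxref, {}, n=10, seed=0)
        assert res.exceedance("adult", "HI") == 1.0
        # scale everything down so HI < 1: exceedance must be exactly 0
        tiny_rice = {m: v * 1e-6 for m, v in c_rice.items()}
        tiny_soil = {m: v * 1e-6 for m, v in c_soil.items()}
        res0 = simulate(tiny_rice, tiny_soil, exposures, toxref, {}, n=10, seed=0)
        assert res0.exceedance("adult", "HI") == 0.0

    def test_lognormal_exceedance_matches_closed_form_tail(self, fixed_inputs):
        # only Cd grain concentration is uncertain; soil contributions are
        # zeroed so HQ_Cd = k * C with k fixed, giving an analytic tail
        c_rice, _, exposures, toxref = fixed_inputs
        c_soil = {m: 0.0 for m in Metal}
        p = exposures["adult"]
        from paddyrisk.core_data import Pathway

        k = p.IR * p.EF * p.ED / (p.BW * p.AT_nc) / toxref.get_rfd(Metal.CD, Pathway.FOOD)
        mu, sigma = np.log(1.0 / k), 0.8  # median of C at the HQ=1 level
        n = 10_000
        spec = DistributionSpec(family="lognormal", mu=mu, sigma=sigma)
        res = simulate(c_rice, c_soil, {"adult": p}, toxref,
                       {"c_rice.Cd": spec}, n=n, seed=11)
        p_true = 1.0 - stats.norm.cdf((np.log(1.0 / k) - mu) / sigma)  # = 0.5
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(res.exceedance("adult", "HQ_Cd") - p_true) < 3 * se

    def test_location_shift_never_decreases_exceedance(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        base_spec = DistributionSpec.lognormal_from_mean_cv(0.5, 0.5)
        up_spec = DistributionSpec(family="lognormal", mu=base_spec.mu + 0.5,
                                   sigma=base_spec.sigma)
        kw = dict(n=2000, seed=13)
        lo = simulate(c_rice, c_soil, exposures, toxref, {"c_rice.Cd": base_spec}, **kw)
        hi = simulate(c_rice, c_soil, exposures, toxref, {"c_rice.Cd": up_spec}, **kw)
        assert hi.exceedance("adult", "HQ_Cd") >= lo.exceedance("adult", "HQ_Cd")

    def test_seed_determinism_bit_identical(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        dists = {"c_soil.Pb": DistributionSpec.lognormal_from_mean_cv(652.34, 0.05),
                 "adult.BW": DistributionSpec.normal(60, 6, lower=20)}
        a = simulate(c_rice, c_soil, exposures, toxref, dists, n=500, seed=21)
        b = simulate(c_rice, c_soil, exposures, toxref, dists, n=500, seed=21)
        assert a.frame.equals(b.frame)

    def test_unknown_parameter_named_in_error(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        with pytest.raises(ValueError, match="c_soil.Hg"):
            simulate(c_rice, c_soil, exposures, toxref,
                     {"c_soil.Hg": DistributionSpec.point(1.0)}, n=10, seed=0)

    def test_percentiles_ordered_and_probabilities_bounded(self, fixed_inputs):
        c_rice, c_soil, exposures, toxref = fixed_inputs
        dists = {"c_soil.As": DistributionSpec.lognormal_from_mean_cv(148.11, 0.3)}
        res = simulate(c_rice, c_soil, exposures, toxref, dists, n=1000, seed=2)
        f = res.frame
        assert ((f["exceedance"] >= 0) & (f["exceedance"] <= 1)).all()
        assert (f["p5"] <= f["p50"]).all() and (f["p50"] <= f["p95"]).all()
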