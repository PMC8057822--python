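import math

import numpy as np
import pandas as pd
import pytest

from airburden.errors import ConfigError, InputError
from airburden.exposure import ExposureField, ExposureMetric
from airburden.grid_io import AgeStructure, Grid, Pollutant, PopulationGrid
from airburden.hia import (
    AGE_BRACKETS,
    BaselineRates,
    GemmParameters,
    OzoneRisk,
    attributable_burden,
    attributable_fraction_from_rr,
    burden_pipeline,
    gemm_rr,
    monte_carlo_regional,
    o3_attributable_fraction,
    o3_hazard_z,
    o3_paf,
    pm25_hazard_z,
    pm25_paf,
    uncertainty_envelope,
)
from airburden.grid_io import RegionMask

from oracles import gemm_rr_scalar


def single_bracket_params(theta=0.1430, lo=None, hi=None):
    lo = theta if lo is None else lo
    hi = theta if hi is None else hi
    table = pd.DataFrame(
        {
            "theta": [theta],
            "theta_lower": [lo],
            "theta_upper": [hi],
            "alpha": [1.6],
            "mu": [15.5],
            "nu": [36.8],
        },
        index=pd.Index(["25-29"], name="age_bracket"),
    )
    return GemmParameters(table)


def single_bracket_rates(mort=2000.0, yll=30000.0, yld=4000.0, rel=0.0, cause="ncd_lri"):
    rows = []
    for metric, mid in (("mort", mort), ("yll", yll), ("yld", yld)):
        rows.append(
            {
                "cause": cause,
                "age_bracket": "25-29",
                "metric": metric,
                "lower": mid * (1 - rel),
                "mid": mid,
                "upper": mid * (1 + rel),
            }
        )
    return BaselineRates.from_per_100k(pd.DataFrame(rows))


def single_bracket_ages(frac=0.6, lo=None, hi=None):
    lo = frac if lo is None else lo
    hi = frac if hi is None else hi
    table = pd.DataFrame(
        {"lower": [lo], "mid": [frac], "upper": [hi]},
        index=pd.Index(["25-29"], name="age_bracket"),
    )
    return AgeStructure(table)


class TestHazardZ:
    @pytest.mark.parametrize(
        "exposure,expected", [(2.4, 0.0), (1.0, 0.0), (72.8, 70.4)]
    )
    def test_pm25_counterfactual_floor(self, exposure, expected):
        assert pm25_hazard_z(exposure, 2.4) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "exposure,expected", [(35.7, 0.0), (20.0, 0.0), (61.3, 25.6)]
    )
    def test_o3_counterfactual_floor(self, exposure, expected):
        assert o3_hazard_z(exposure, 35.7) == pytest.approx(expected)


class TestGemmRR:
    def test_rr_is_one_at_zero_excess(self):
        params = GemmParameters.load()
        for b in params.brackets:
            assert gemm_rr(0.0, params, b) == 1.0

    def test_matches_independent_evaluation(self):
        params = single_bracket_params(theta=0.1430)
        got = float(gemm_rr(70.4, params, "25-29"))
        expected = gemm_rr_scalar(70.4, 0.1430, 1.6, 15.5, 36.8)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(1.5595, abs=5e-5)

    def test_log_rr_linear_in_theta(self):
        p1 = single_bracket_params(theta=0.07)
        p2 = single_bracket_params(theta=0.14)
        z = 55.0
        assert math.log(gemm_rr(z, p2, "25-29")) == pytest.approx(
            2 * math.log(gemm_rr(z, p1, "25-29"))
        )

    def test_strictly_increasing_in_z(self):
        params = GemmParameters.load()
        z = np.linspace(0.0, 150.0, 400)
        rr = gemm_rr(z, params, "60-64")
        assert (np.diff(rr) > 0).all()
        assert (rr >= 1.0).all()

    def test_unknown_bracket_rejected(self):
        with pytest.raises(ConfigError):
            gemm_rr(10.0, GemmParameters.load(), "0-4")


class TestPaf:
    def test_null_risk_gives_zero(self):
        params = single_bracket_params()
        assert pm25_paf(0.0, params, "25-29", 1000.0) == 0.0

    def test_fraction_algebra_rr_two(self):
        assert attributable_fraction_from_rr(2.0) * 1000 == pytest.approx(500.0)

    def test_pm25_count_matches_oracle(self):
        params = single_bracket_params(theta=0.1430)
        rr = gemm_rr_scalar(70.4, 0.1430, 1.6, 15.5, 36.8)
        got = pm25_paf(70.4, params, "25-29", 100_000.0)
        assert got == pytest.approx((1 - 1 / rr) * 100_000.0, rel=1e-12)
        # 35,878.2 persons at full precision (a 4-digit-rounded RR gives 35,877)
        assert round(float(got)) == 35878

    def test_o3_zero_excess(self):
        assert o3_paf(0.0, OzoneRisk(), 1000.0) == 0.0

    def test_o3_ten_ppb_identity(self):
        # exp(-ln(HR)) = 1/HR, so at z = 10 the fraction is 1 - 1/HR
        frac = o3_attributable_fraction(10.0, OzoneRisk())
        assert frac == pytest.approx(1 - 1 / 1.06, rel=1e-12)

    def test_o3_count_matches_direct_evaluation(self):
        got = o3_paf(25.6, OzoneRisk(), 100_000.0)
        expected = (1 - math.exp(-25.6 * math.log(1.06) / 10)) * 100_000.0
        assert got == pytest.approx(expected, rel=1e-12)
        assert round(float(got)) == 13858  # 13,857.6 persons

    def test_small_z_first_order_linearity(self):
        risk = OzoneRisk()
        for z in (0.1, 0.5, 1.0):
            approx = z * math.log(1.06) / 10
            assert o3_attributable_fraction(z, risk) == pytest.approx(approx, rel=0.01)

    def test_fractions_within_unit_interval(self):
        params = GemmParameters.load()
        z = np.linspace(0, 500, 200)
        for b in ("25-29", "80+"):
            af = attributable_fraction_from_rr(gemm_rr(z, params, b, "upper"))
            assert ((af >= 0) & (af < 1)).all()
        af = o3_attributable_fraction(np.linspace(0, 200, 100), OzoneRisk(), "upper")
        assert ((af >= 0) & (af < 1)).all()


class TestAttributableBurden:
    def test_zero_paf_gives_zero_everywhere(self):
        rates = single_bracket_rates()
        for metric in ("mort", "yll", "yld", "daly"):
            assert attributable_burden(0.0, rates, "ncd_lri", "25-29", metric) == 0.0

    def test_hand_multiplication(self):
        rates = single_bracket_rates(mort=2000.0)
        got = attributable_burden(17_938.5, rates, "ncd_lri", "25-29", "mort")
        assert got == pytest.approx(358.77)

    def test_daly_is_yll_plus_yld(self):
        rates = single_bracket_rates(yll=100.0, yld=20.0)
        paf = 100_000.0
        assert attributable_burden(paf, rates, "ncd_lri", "25-29", "daly") == pytest.approx(
            100.0 + 20.0
        )


def one_cell_inputs(pm25=72.8, o3=61.3, pop=100_000.0, **kw):
    grid = Grid(np.array([30.0]), np.array([110.0]))
    pm = ExposureField(
        grid, Pollutant.PM25, ExposureMetric.ANNUAL_MEAN_PM25, np.array([[pm25]])
    )
    oz = ExposureField(
        grid, Pollutant.O3, ExposureMetric.SIX_M_DM8H_O3, np.array([[o3]])
    )
    population = PopulationGrid(grid, np.array([[pop]]))
    return grid, pm, oz, population


def both_cause_rates(rel=0.0):
    rows = []
    for cause, mort, yll, yld in (("ncd_lri", 2000.0, 30000.0, 4000.0), ("copd", 150.0, 1800.0, 500.0)):
        for metric, mid in (("mort", mort), ("yll", yll), ("yld", yld)):
            rows.append(
                {
                    "cause": cause,
                    "age_bracket": "25-29",
                    "metric": metric,
                    "lower": mid * (1 - rel),
                    "mid": mid,
                    "upper": mid * (1 + rel),
                }
            )
    return BaselineRates.from_per_100k(pd.DataFrame(rows))


class TestBurdenPipeline:
    def test_exposure_at_counterfactual_gives_zero_burden(self):
        _, pm, oz, pop = one_cell_inputs(pm25=2.4, o3=35.7)
        result = burden_pipeline(
            pm, oz, pop, single_bracket_ages(), both_cause_rates(),
            single_bracket_params(), OzoneRisk(),
        )
        assert float(np.abs(result.counts.values).max()) == 0.0

    def test_single_cell_chain_matches_hand_computation(self):
        _, pm, oz, pop = one_cell_inputs(pm25=72.8, o3=61.3, pop=100_000.0)
        ages = single_bracket_ages(frac=0.6)
        rates = both_cause_rates()
        result = burden_pipeline(
            pm, oz, pop, ages, rates, single_bracket_params(0.1430), OzoneRisk()
        )
        # hand chain, PM2.5: z = 70.4; RR; PAF = 60,000 * (1 - 1/RR)
        rr = gemm_rr_scalar(70.4, 0.1430, 1.6, 15.5, 36.8)
        paf_pm = 60_000.0 * (1 - 1 / rr)
        mort_pm = paf_pm * 2000.0 / 100_000.0
        got_mort = float(result.counts.sel(variant="mid", cause="ncd_lri", metric="mort").sum())
        assert got_mort == pytest.approx(mort_pm, rel=1e-12)
        # hand chain, O3: z = 25.6
        paf_o3 = 60_000.0 * (1 - math.exp(-25.6 * math.log(1.06) / 10.0))
        yll_o3 = paf_o3 * 1800.0 / 100_000.0
        yld_o3 = paf_o3 * 500.0 / 100_000.0
        got_daly = float(result.counts.sel(variant="mid", cause="copd", metric="daly").sum())
        assert got_daly == pytest.approx(yll_o3 + yld_o3, rel=1e-12)

    def test_linear_in_population_and_rates(self):
        grid, pm, oz, pop = one_cell_inputs()
        ages = single_bracket_ages()
        params = single_bracket_params()
        base = burden_pipeline(pm, oz, pop, ages, both_cause_rates(), params, OzoneRisk())
        pop2 = PopulationGrid(grid, pop.counts * 3.0)
        scaled = burden_pipeline(pm, oz, pop2, ages, both_cause_rates(), params, OzoneRisk())
        assert np.allclose(scaled.counts.values, 3.0 * base.counts.values, rtol=1e-12)
        # scaling every baseline rate by k scales all counts by k
        rows = both_cause_rates()._table.copy()
        rows[["lower", "mid", "upper"]] *= 5.0
        scaled_rates = BaselineRates(rows)
        out = burden_pipeline(pm, oz, pop, ages, scaled_rates, params, OzoneRisk())
        assert np.allclose(out.counts.values, 5.0 * base.counts.values, rtol=1e-12)

    def test_counts_never_exceed_bracket_population(self):
        _, pm, oz, pop = one_cell_inputs(pm25=500.0, pop=1000.0)
        ages = single_bracket_ages(frac=0.6)
        rates = single_bracket_rates(mort=100_000.0)  # rate of 1 per person
        result = burden_pipeline(
            pm, None, pop, ages, rates, single_bracket_params(0.1585), None
        )
        mort = float(result.counts.sel(variant="mid", cause="ncd_lri", metric="mort").sum())
        assert 0 <= mort < 600.0  # bracket population

    def test_daly_identity_everywhere(self):
        _, pm, oz, pop = one_cell_inputs()
        result = burden_pipeline(
            pm, oz, pop,
            single_bracket_ages(0.6, 0.55, 0.65),
            both_cause_rates(rel=0.1),
            single_bracket_params(0.1430, 0.11, 0.18),
            OzoneRisk(),
        )
        daly = result.counts.sel(metric="daly")
        yll = result.counts.sel(metric="yll")
        yld = result.counts.sel(metric="yld")
        assert np.array_equal(daly.values, (yll + yld).values)

    def test_bracket_mismatch_raises(self):
        _, pm, oz, pop = one_cell_inputs()
        table = pd.DataFrame(
            {"lower": [0.5], "mid": [0.5], "upper": [0.5]},
            index=pd.Index(["95+"], name="age_bracket"),
        )
        with pytest.raises(ConfigError):
            burden_pipeline(
                pm, oz, pop, AgeStructure(table), both_cause_rates(),
                single_bracket_params(), OzoneRisk(),
            )


class TestUncertaintyEnvelope:
    def test_degenerate_variants_collapse(self):
        _, pm, oz, pop = one_cell_inputs()
        result = uncertainty_envelope(
            pm, oz, pop, single_bracket_ages(), both_cause_rates(),
            single_bracket_params(), OzoneRisk(1.06, 1.06, 1.06),
        )
        lo = result.counts.sel(variant="lower").values
        mi = result.counts.sel(variant="mid").values
        hi = result.counts.sel(variant="upper").values
        assert np.array_equal(lo, mi) and np.array_equal(mi, hi)

    def test_envelope_ordering_and_theta_monotonicity(self):
        _, pm, oz, pop = one_cell_inputs()
        narrow = uncertainty_envelope(
            pm, oz, pop, single_bracket_ages(0.6, 0.58, 0.62),
            both_cause_rates(rel=0.05),
            single_bracket_params(0.143, 0.14, 0.15), OzoneRisk(),
        )
        wide = uncertainty_envelope(
            pm, oz, pop, single_bracket_ages(0.6, 0.58, 0.62),
            both_cause_rates(rel=0.05),
            single_bracket_params(0.143, 0.10, 0.19), OzoneRisk(),
        )
        for res in (narrow, wide):
            lo = res.counts.sel(variant="lower").values
            mi = res.counts.sel(variant="mid").values
            hi = res.counts.sel(variant="upper").values
            assert (lo <= mi + 1e-12).all() and (mi <= hi + 1e-12).all()
        n_lo = narrow.counts.sel(variant="lower", cause="ncd_lri").values
        w_lo = wide.counts.sel(variant="lower", cause="ncd_lri").values
        n_hi = narrow.counts.sel(variant="upper", cause="ncd_lri").values
        w_hi = wide.counts.sel(variant="upper", cause="ncd_lri").values
        assert (w_lo <= n_lo + 1e-12).all() and (w_hi >= n_hi - 1e-12).all()

    def test_envelope_equals_brute_force_over_27_combinations(self):
        _, pm, oz, pop = one_cell_inputs()
        ages_b = dict(frac=0.6, lo=0.55, hi=0.65)
        params_b = dict(theta=0.143, lo=0.11, hi=0.18)
        rel = 0.1

        env = uncertainty_envelope(
            pm, oz, pop,
            single_bracket_ages(ages_b["frac"], ages_b["lo"], ages_b["hi"]),
            both_cause_rates(rel=rel),
            single_bracket_params(params_b["theta"], params_b["lo"], params_b["hi"]),
            OzoneRisk(),
        )
        totals = {
            v: float(env.counts.sel(variant=v, cause="ncd_lri", metric="mort").sum())
            for v in ("lower", "mid", "upper")
        }

        theta_by = {"lower": 0.11, "mid": 0.143, "upper": 0.18}
        frac_by = {"lower": 0.55, "mid": 0.6, "upper": 0.65}
        rate_by = {"lower": 1 - rel, "mid": 1.0, "upper": 1 + rel}
        brute = []
        for tv in ("lower", "mid", "upper"):
            for rv in ("lower", "mid", "upper"):
                for av in ("lower", "mid", "upper"):
                    rr = gemm_rr_scalar(70.4, theta_by[tv], 1.6, 15.5, 36.8)
                    paf = 100_000.0 * frac_by[av] * (1 - 1 / rr)
                    brute.append(paf * 2000.0 * rate_by[rv] / 100_000.0)
        assert totals["lower"] == pytest.approx(min(brute), rel=1e-12)
        assert totals["upper"] == pytest.approx(max(brute), rel=1e-12)


class TestMonteCarlo:
    def test_regional_draws_bracket_mid_and_are_deterministic(self):
        grid, pm, oz, pop = one_cell_inputs()
        mask = RegionMask("all", np.ones(grid.shape))
        kwargs = dict(
            pop=pop,
            ages=single_bracket_ages(0.6, 0.58, 0.62),
            rates=both_cause_rates(rel=0.08),
            masks=[mask],
            gemm=single_bracket_params(0.143, 0.12, 0.17),
            ozone_risk=OzoneRisk(),
            n_draws=50,
            seed=123,
        )
        df1 = monte_carlo_regional(pm, oz, **kwargs)
        df2 = monte_carlo_regional(pm, oz, **kwargs)
        pd.testing.assert_frame_equal(df1, df2)
        assert (df1["lower"] <= df1["upper"]).all()
        row = df1[(df1.cause == "ncd_lri") & (df1.metric == "mort")].iloc[0]
        assert row["lower"] <= row["mid"] <= row["upper"]


class TestParameterValidation:
    def test_theta_bounds_must_bracket(self):
        with pytest.raises(ConfigError):
            single_bracket_params(0.14, lo=0.15, hi=0.16)

    def test_ozone_hr_ordering_enforced(self):
        with pytest.raises(ConfigError):
            OzoneRisk(hr=1.06, hr_lower=1.08, hr_upper=1.10)

    def test_missing_cause_in_rates(self):
        rates = single_bracket_rates(cause="ncd_lri")
        with pytest.raises(ConfigError):
            rates.rate("copd", "mort", ["25-29"])

    def test_negative_rates_rejected(self):
        df = pd.DataFrame(
            [{"cause": "ncd_lri", "age_bracket": "25-29", "metric": "mort",
              "lower": -1.0, "mid": 1.0, "upper": 2.0}]
        )
        with pytest.raises(InputError):
            BaselineRates.from_per_100k(df)

    def test_packaged_parameters_cover_all_brackets(self):
        params = GemmParameters.load()
        assert list(params.brackets) == list(AGE_BRACKETS)
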