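"""Attributable-burden computation for PM2.5 and ozone exposure.

PM2.5 risk follows the Global Exposure Mortality Model (GEMM) for
non-communicable disease plus lower respiratory infection (NCD+LRI):

    z  = max(0, PM2.5 - cf),            cf = 2.4 ug m-3
    RR = exp[ theta * ln(1 + z/alpha) / (1 + exp((mu - z)/nu)) ]
    attributable count = P * (1 - 1/RR)

with age-bracket-specific theta (5-year brackets, 25 to 80+) and shared
alpha, mu, nu. Ozone risk for chronic obstructive pulmonary disease (COPD)
uses a log-linear hazard ratio per 10 ppb of 6mDM8h exposure above a
counterfactual of 35.7 ppb:

    z = max(0, O3 - cf);  attributable count = P * (1 - exp(-z * ln(HR)/10))

Burden per metric is attributable count times the per-person baseline rate:
MORT, YLL and YLD are products with I_MORT, I_YLL and I_YLD, and DALYs are
YLL + YLD. Uncertainty envelopes evaluate the exposure-outcome association,
baseline rates and age fractions simultaneously at their lower/mid/upper
bounds; a Monte-Carlo combination over regional aggregates is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigError, InputError
from .exposure import ExposureField
from .grid_io import AgeStructure, Grid, PopulationGrid

AGE_BRACKETS = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)
VARIANTS = ("lower", "mid", "upper")
CAUSE_PM25 = "ncd_lri"
CAUSE_O3 = "copd"
METRICS = ("mort", "yll", "yld", "daly")

DEFAULT_CF_PM25 = 2.4  # ug m-3, exposure level below which no excess risk is assumed
DEFAULT_CF_O3 = 35.7  # ppb


class GemmParameters:
    """GEMM hazard-function parameters per age bracket.

    Backed by a table indexed by bracket with columns ``theta``,
    ``theta_lower``, ``theta_upper``, ``alpha``, ``mu``, ``nu``. The packaged
    default file carries the NCD+LRI fit including the China cohort; it is an
    editable CSV so alternative fits can be swapped in without code changes.
    """

    REQUIRED = ("theta", "theta_lower", "theta_upper", "alpha", "mu", "nu")

    def __init__(self, table: pd.DataFrame, counterfactual: float = DEFAULT_CF_PM25):
        missing = set(self.REQUIRED) - set(table.columns)
        if missing:
            raise ConfigError(f"GEMM table missing columns: {sorted(missing)}")
        if (table["alpha"] <= 0).any() or (table["nu"] <= 0).any():
            raise ConfigError("GEMM alpha and nu must be positive")
        bad = ~(
            (table["theta_lower"] <= table["theta"])
            & (table["theta"] <= table["theta_upper"])
        )
        if bad.any():
            raise ConfigError("GEMM theta bounds must bracket the central value")
        if counterfactual < 0:
            raise ConfigError("counterfactual must be non-negative")
        self.table = table
        self.counterfactual = float(counterfactual)

    @property
    def brackets(self) -> list[str]:
        return list(self.table.index)

    def theta(self, bracket: str, variant: str = "mid") -> float:
        if bracket not in self.table.index:
            raise ConfigError(f"unknown age bracket {bracket!r}")
        col = {"lower": "theta_lower", "mid": "theta", "upper": "theta_upper"}[variant]
        return float(self.table.loc[bracket, col])

    def shape(self, bracket: str) -> tuple[float, float, float]:
        if bracket not in self.table.index:
            raise ConfigError(f"unknown age bracket {bracket!r}")
        row = self.table.loc[bracket]
        return float(row["alpha"]), float(row["mu"]), float(row["nu"])

    @classmethod
    def from_csv(cls, path, counterfactual: float = DEFAULT_CF_PM25) -> "GemmParameters":
        return cls(pd.read_csv(path, index_col="age_bracket"), counterfactual)

    @classmethod
    def load(cls, counterfactual: float = DEFAULT_CF_PM25) -> "GemmParameters":
        """Load the packaged default parameter file."""
        ref = resources.files("airburden").joinpath("data/gemm_ncd_lri.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path, counterfactual)


@dataclass(frozen=True)
class OzoneRisk:
    """Log-linear COPD hazard ratio per 10 ppb of 6mDM8h ozone."""

    hr: float = 1.06
    hr_lower: float = 1.02
    hr_upper: float = 1.10
    counterfactual: float = DEFAULT_CF_O3
    cause: str = CAUSE_O3

    def __post_init__(self):
        if not (1.0 < self.hr_lower <= self.hr <= self.hr_upper):
            raise ConfigError("ozone HR bounds must satisfy 1 < lower <= mid <= upper")
        if self.counterfactual < 0:
            raise ConfigError("counterfactual must be non-negative")

    def hazard_ratio(self, variant: str = "mid") -> float:
        return {"lower": self.hr_lower, "mid": self.hr, "upper": self.hr_upper}[variant]


class BaselineRates:
    """Cause x age-bracket x metric baseline rates with uncertainty bounds.

    Constructed from a long table with columns ``cause``, ``age_bracket``,
    ``metric`` (mort/yll/yld), ``lower``, ``mid``, ``upper`` given per
    100,000 persons per year. Rates are divided by 100,000 exactly once, at
    ingestion; every accessor returns per-person rates.
    """

    def __init__(self, per_person: pd.DataFrame):
        self._table = per_person

    @classmethod
    def from_per_100k(cls, table: pd.DataFrame) -> "BaselineRates":
        required = {"cause", "age_bracket", "metric", "lower", "mid", "upper"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"rate table missing columns: {sorted(missing)}")
        t = table.copy()
        if (t[["lower", "mid", "upper"]] < 0).any().any():
            raise InputError("baseline rates must be non-negative")
        if not ((t["lower"] <= t["mid"]) & (t["mid"] <= t["upper"])).all():
            raise InputError("baseline rates must satisfy lower <= mid <= upper")
        t[["lower", "mid", "upper"]] /= 100_000.0
        return cls(t.set_index(["cause", "age_bracket", "metric"]).sort_index())

    @classmethod
    def from_csv(cls, path) -> "BaselineRates":
        return cls.from_per_100k(pd.read_csv(path))

    def to_csv(self, path) -> None:
        out = self._table.reset_index()
        out[["lower", "mid", "upper"]] *= 100_000.0
        out.to_csv(path, index=False)

    def causes(self) -> list[str]:
        return sorted({c for c, _, _ in self._table.index})

    def rate(
        self, cause: str, metric: str, brackets, variant: str = "mid"
    ) -> np.ndarray:
        """Per-person rates for one cause/metric over the given brackets."""
        try:
            sub = self._table.loc[cause].loc[:, variant]
        except KeyError as e:
            raise ConfigError(f"no baseline rates for cause {cause!r}") from e
        out = np.empty(len(brackets))
        for k, b in enumerate(brackets):
            try:
                out[k] = sub.loc[(b, metric)]
            except KeyError as e:
                raise ConfigError(
                    f"no baseline {metric!r} rate for cause {cause!r}, bracket {b!r}"
                ) from e
        return out


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def pm25_hazard_z(exposure, cf: float = DEFAULT_CF_PM25):
    """Excess PM2.5 exposure above the counterfactual: max(0, PM2.5 - cf)."""
    return np.maximum(0.0, np.asarray(exposure, dtype=float) - cf)


def o3_hazard_z(exposure, cf: float = DEFAULT_CF_O3):
    """Excess 6mDM8h ozone exposure above the counterfactual."""
    return np.maximum(0.0, np.asarray(exposure, dtype=float) - cf)


def gemm_rr(z, params: GemmParameters, bracket: str, variant: str = "mid"):
    """GEMM relative risk at excess exposure ``z`` for one age bracket."""
    theta = params.theta(bracket, variant)
    alpha, mu, nu = params.shape(bracket)
    z = np.asarray(z, dtype=float)
    weight = 1.0 / (1.0 + np.exp((mu - z) / nu))
    return np.exp(theta * np.log1p(z / alpha) * weight)


def attributable_fraction_from_rr(rr):
    """PAF-style attributable fraction 1 - 1/RR."""
    return 1.0 - 1.0 / np.asarray(rr, dtype=float)


def pm25_paf(z, params: GemmParameters, bracket: str, population, variant: str = "mid"):
    """Attributable person count P * (1 - 1/RR) for one bracket."""
    rr = gemm_rr(z, params, bracket, variant)
    return np.asarray(population, dtype=float) * attributable_fraction_from_rr(rr)


def o3_attributable_fraction(z, risk: OzoneRisk, variant: str = "mid"):
    """Ozone attributable fraction 1 - exp(-z * ln(HR) / 10)."""
    hr = risk.hazard_ratio(variant)
    return 1.0 - np.exp(-np.asarray(z, dtype=float) * np.log(hr) / 10.0)


def o3_paf(z, risk: OzoneRisk, population, variant: str = "mid"):
    """Attributable person count for ozone exposure."""
    return np.asarray(population, dtype=float) * o3_attributable_fraction(z, risk, variant)


def attributable_burden(
    paf_count, rates: BaselineRates, cause: str, bracket: str, metric: str,
    variant: str = "mid",
):
    """Attributable amount for one metric: PAF count x per-person rate.

    ``metric="daly"`` returns the sum of the YLL and YLD products.
    """
    paf_count = np.asarray(paf_count, dtype=float)
    if metric == "daly":
        return attributable_burden(
            paf_count, rates, cause, bracket, "yll", variant
        ) + attributable_burden(paf_count, rates, cause, bracket, "yld", variant)
    rate = rates.rate(cause, metric, [bracket], variant)[0]
    return paf_count * rate


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class BurdenResult:
    """Attributable burden per variant x cause x metric x age x cell.

    ``counts`` is an :class:`xarray.DataArray` with dimensions
    ``(variant, cause, metric, age, lat, lon)``; DALYs equal YLL + YLD by
    construction.
    """

    grid: Grid
    counts: xr.DataArray
    scenario_id: str = "control"

    def total(
        self, cause: str | None = None, metric: str = "mort", variant: str = "mid"
    ) -> np.ndarray:
        """Per-cell total over age brackets (and causes when ``cause`` is None)."""
        da = self.counts.sel(variant=variant, metric=metric)
        if cause is not None:
            da = da.sel(cause=cause)
            return da.sum("age").values
        return da.sum(["cause", "age"]).values

    def national(
        self, cause: str | None = None, metric: str = "mort", variant: str = "mid"
    ) -> float:
        return float(self.total(cause, metric, variant).sum())


def _bracket_population(
    pop: PopulationGrid, ages: AgeStructure, variant: str
) -> np.ndarray:
    """(age, lat, lon) person counts: grid count times national age fraction."""
    frac = ages.fractions(variant)
    return frac[:, None, None] * pop.counts[None, :, :]


def burden_pipeline(
    pm25_exposure: ExposureField | None,
    o3_exposure: ExposureField | None,
    pop: PopulationGrid,
    ages: AgeStructure,
    rates: BaselineRates,
    gemm: GemmParameters | None = None,
    ozone_risk: OzoneRisk | None = None,
    variants=VARIANTS,
) -> BurdenResult:
    """Full chain from exposure fields to a per-cell burden with envelopes.

    Each requested variant evaluates the exposure-outcome association, the
    baseline rates and the age fractions simultaneously at that bound, which
    is the conservative envelope combination (the chain is monotone in each
    source, so this brackets all mixed combinations).
    """
    if pm25_exposure is None and o3_exposure is None:
        raise InputError("at least one exposure field is required")
    ref = pm25_exposure if pm25_exposure is not None else o3_exposure
    grid = ref.grid
    scenario_id = ref.scenario_id
    if gemm is None:
        gemm = GemmParameters.load()
    if ozone_risk is None:
        ozone_risk = OzoneRisk()

    brackets = list(ages.brackets)
    if pm25_exposure is not None and set(brackets) - set(gemm.brackets):
        raise ConfigError("age structure brackets missing from GEMM parameters")

    causes = []
    if pm25_exposure is not None:
        causes.append(CAUSE_PM25)
    if o3_exposure is not None:
        causes.append(CAUSE_O3)

    data = np.zeros(
        (len(variants), len(causes), len(METRICS), len(brackets), *grid.shape)
    )
    for vi, variant in enumerate(variants):
        bracket_pop = _bracket_population(pop, ages, variant)
        for ci, cause in enumerate(causes):
            if cause == CAUSE_PM25:
                z = pm25_hazard_z(pm25_exposure.values, gemm.counterfactual)
                af = np.stack(
                    [
                        attributable_fraction_from_rr(gemm_rr(z, gemm, b, variant))
                        for b in brackets
                    ]
                )  # (age, lat, lon)
            else:
                z = o3_hazard_z(o3_exposure.values, ozone_risk.counterfactual)
                af = np.broadcast_to(
                    o3_attributable_fraction(z, ozone_risk, variant),
                    (len(brackets), *grid.shape),
                )
            paf = bracket_pop * af
            for mi, metric in enumerate(("mort", "yll", "yld")):
                rate = rates.rate(cause, metric, brackets, variant)
                data[vi, ci, mi] = paf * rate[:, None, None]
            data[vi, ci, METRICS.index("daly")] = (
                data[vi, ci, METRICS.index("yll")] + data[vi, ci, METRICS.index("yld")]
            )

    counts = xr.DataArray(
        data,
        dims=("variant", "cause", "metric", "age", "lat", "lon"),
        coords={
            "variant": list(variants),
            "cause": causes,
            "metric": list(METRICS),
            "age": brackets,
            "lat": grid.lat_centers,
            "lon": grid.lon_centers,
        },
        name="attributable_burden",
    )
    return BurdenResult(grid=grid, counts=counts, scenario_id=scenario_id)


def uncertainty_envelope(
    pm25_exposure,
    o3_exposure,
    pop: PopulationGrid,
    ages: AgeStructure,
    rates: BaselineRates,
    gemm: GemmParameters | None = None,
    ozone_risk: OzoneRisk | None = None,
) -> BurdenResult:
    """(lower, mid, upper) burden with all three sources at matching bounds."""
    return burden_pipeline(
        pm25_exposure, o3_exposure, pop, ages, rates, gemm, ozone_risk,
        variants=VARIANTS,
    )


def monte_carlo_regional(
    pm25_exposure,
    o3_exposure,
    pop: PopulationGrid,
    ages: AgeStructure,
    rates: BaselineRates,
    masks,
    gemm: GemmParameters | None = None,
    ozone_risk: OzoneRisk | None = None,
    n_draws: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo 95UI on regional totals (optional alternative to the envelope).

    Draws theta per bracket and ln(HR) from normals whose 2.5/97.5 percentiles
    match the configured bounds, and scales rates and age fractions by
    normal factors derived from their bounds. Returns a long DataFrame
    (region, cause, metric) with mid (central parameters) and the 2.5/97.5
    percentiles of the draws.
    """
    rng = np.random.default_rng(seed)
    if gemm is None:
        gemm = GemmParameters.load()
    if ozone_risk is None:
        ozone_risk = OzoneRisk()
    masks = list(masks)

    mid = burden_pipeline(
        pm25_exposure, o3_exposure, pop, ages, rates, gemm, ozone_risk,
        variants=("mid",),
    )
    causes = list(mid.counts.coords["cause"].values)

    def _regional(result):
        rows = {}
        for m in masks:
            for cause in causes:
                for metric in METRICS:
                    cell = result.total(cause, metric, result.counts.variant.values[0])
                    rows[(m.region_id, cause, metric)] = float(
                        (cell * m.weights).sum()
                    )
        return rows

    draws = []
    table = gemm.table
    theta_se = (table["theta_upper"] - table["theta_lower"]) / (2 * 1.96)
    log_hr_se = (np.log(ozone_risk.hr_upper) - np.log(ozone_risk.hr_lower)) / (2 * 1.96)
    for _ in range(n_draws):
        t_draw = table.copy()
        theta_d = rng.normal(table["theta"], theta_se)
        t_draw["theta"] = t_draw["theta_lower"] = t_draw["theta_upper"] = np.maximum(
            theta_d, 0.0
        )
        gemm_d = GemmParameters(t_draw, gemm.counterfactual)
        hr_d = float(np.exp(rng.normal(np.log(ozone_risk.hr), log_hr_se)))
        hr_d = max(hr_d, 1.0 + 1e-9)
        risk_d = OzoneRisk(hr_d, hr_d, hr_d, ozone_risk.counterfactual)
        # scale rates and age fractions by one normal factor per source
        rate_f = max(0.0, rng.normal(1.0, _half_width(rates), 1)[0])
        age_f = max(0.0, rng.normal(1.0, _age_half_width(ages), 1)[0])
        t = rates._table.copy()
        scaled = t["mid"].to_numpy() * rate_f
        for col in ("lower", "mid", "upper"):
            t[col] = scaled
        rates_d = BaselineRates(t)
        at = ages.table.copy()
        at["lower"] = at["mid"] = at["upper"] = np.minimum(
            ages.table["mid"] * age_f, 1.0
        )
        ages_d = AgeStructure(at)
        res = burden_pipeline(
            pm25_exposure, o3_exposure, pop, ages_d, rates_d, gemm_d, risk_d,
            variants=("mid",),
        )
        draws.append(_regional(res))

    keys = sorted(draws[0])
    mid_rows = _regional(mid)
    records = []
    for key in keys:
        vals = np.array([d[key] for d in draws])
        records.append(
            {
                "region": key[0],
                "cause": key[1],
                "metric": key[2],
                "lower": float(np.percentile(vals, 2.5)),
                "mid": mid_rows[key],
                "upper": float(np.percentile(vals, 97.5)),
            }
        )
    return pd.DataFrame.from_records(records)


def _half_width(rates: BaselineRates) -> float:
    t = rates._table
    mid = t["mid"].replace(0, np.nan)
    rel = ((t["upper"] - t["lower"]) / (2 * 1.96) / mid).dropna()
    return float(rel.mean()) if len(rel) else 0.0


def _age_half_width(ages: AgeStructure) -> float:
    t = ages.table
    mid = t["mid"].replace(0, np.nan)
    rel = ((t["upper"] - t["lower"]) / (2 * 1.96) / mid).dropna()
    return float(rel.mean()) if len(rel) else 0.0
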