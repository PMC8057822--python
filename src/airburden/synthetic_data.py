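"""Synthetic study-world generator.

Stands in for the chemistry-transport simulation and the external population
and health data: it builds a regular lat/lon domain with urban-concentrated
population, an adult age structure, cause-specific baseline rate tables, a
regional partition with a small focal ("GBA-like") sub-domain, hourly PM2.5
and ozone concentration fields with diurnal/seasonal cycles and
autocorrelated noise, sector-scaled policy scenarios, and noisy station
observations. Every output is a pure function of the configuration seed.

Chemistry is replaced by a linear source surrogate: each sector contributes
a separable (spatial pattern) x (temporal modulation) component, and a
scenario subtracts a scaled component within its spatial domain. Ozone
carries an explicit signed regime map — cells flagged "VOC-limited" respond
to precursor (NOx/NH3) cuts with an ozone increase, the "NOx-limited"
remainder with a decrease — so the qualitative scenario behaviour of real
assessments (ozone rising under transport or agricultural cuts while PM2.5
falls) is reproducible at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from .grid_io import (
    AgeStructure,
    ConcentrationField,
    Grid,
    Pollutant,
    PopulationGrid,
    RegionMask,
    StationRecord,
)
from .hia import AGE_BRACKETS, BaselineRates

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorSpec:
    """Sector contribution shares and qualitative behaviour.

    ``o3_signed`` marks precursor sectors (NOx, NH3) whose cuts raise ozone
    in VOC-limited cells; unsigned sectors always lower ozone when cut.
    ``spatial`` selects the emission footprint: population-following
    ("urban"), inverse-population ("rural") or a blend ("mixed").
    """

    share_pm25: float
    share_o3: float
    spatial: str = "mixed"
    o3_signed: bool = False


@dataclass(frozen=True)
class ScenarioDef:
    """A sector-scaled perturbation: reduce ``sector`` by ``scale`` in ``domain``."""

    name: str
    sector: str
    scale: float
    domain: str = "national"  # national | inside_focal | outside_focal

    def __post_init__(self):
        if not 0.0 <= self.scale <= 1.0:
            raise ConfigError("scenario scaling must lie in [0, 1]")
        if self.domain not in ("national", "inside_focal", "outside_focal"):
            raise ConfigError(f"unknown scenario domain {self.domain!r}")


def _default_sectors() -> dict[str, SectorSpec]:
    # PM2.5 shares make the residential sector the largest national
    # contributor; transport's PM2.5 share is small (nitrate-mediated) while
    # its ozone-precursor share is large, mirroring the qualitative sector
    # structure of Chinese emission inventories.
    return {
        "residential": SectorSpec(0.35, 0.15, "mixed", o3_signed=False),
        "industry": SectorSpec(0.20, 0.25, "urban", o3_signed=False),
        "transport": SectorSpec(0.05, 0.30, "urban", o3_signed=True),
        "agriculture": SectorSpec(0.15, 0.05, "rural", o3_signed=True),
        "other": SectorSpec(0.25, 0.25, "mixed", o3_signed=False),
    }


def _default_scenarios() -> tuple[ScenarioDef, ...]:
    # archetypes of the four national policy levers: a 50% residential
    # solid-fuel transition and 30% agricultural NH3 cut outside the focal
    # region, and nationwide 10% industrial-VOC and 80% transport-NOx cuts
    return (
        ScenarioDef("RES", "residential", 0.50, "outside_focal"),
        ScenarioDef("IND-CHN", "industry", 0.10, "national"),
        ScenarioDef("TRA-CHN", "transport", 0.80, "national"),
        ScenarioDef("AGR", "agriculture", 0.30, "outside_focal"),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of the synthetic study world.

    Defaults define the study conditions: a 24 x 36 cell domain over a
    China-like extent, one complete simulated year at hourly resolution,
    population-weighted control exposures of roughly 70-80 ug m-3 PM2.5 and
    60 ppb 6mDM8h ozone, and the four scenario archetypes.
    """

    seed: int = 0
    n_lat: int = 24
    n_lon: int = 36
    lat_min: float = 18.0
    lat_max: float = 42.0
    lon_min: float = 96.0
    lon_max: float = 132.0
    year: int = 2015

    background_pm25: float = 12.0  # ug m-3 regional background
    background_o3: float = 30.0  # ppb
    sector_total_pm25: float = 60.0  # national PW sector-attributable PM2.5
    sector_total_o3: float = 28.0  # ppb, sector-attributable 6mDM8h-scale ozone
    diurnal_amp_pm25: float = 0.20
    seasonal_amp_pm25: float = 0.30
    diurnal_amp_o3: float = 0.35
    seasonal_amp_o3: float = 0.25
    noise_sd_pm25: float = 4.0
    noise_sd_o3: float = 3.0
    noise_rho: float = 0.9  # hourly AR(1) autocorrelation

    total_population: float = 1.37e9
    urban_share: float = 0.60
    n_urban_centers: int = 8
    urban_sigma_cells: float = 1.2
    rural_smooth_sigma: float = 3.0

    sectors: dict[str, SectorSpec] = field(default_factory=_default_sectors)
    scenarios: tuple[ScenarioDef, ...] = field(default_factory=_default_scenarios)
    voc_limited_fraction: float = 0.30  # population-densest cells respond inversely

    n_stations: int = 50
    station_bias_mean: float = 0.0  # multiplicative observation bias (1 + b)
    station_bias_sd: float = 0.05
    station_noise_sd: float = 5.0  # additive hourly noise, ug m-3
    station_missing_frac: float = 0.05

    def __post_init__(self):
        for pol in ("pm25", "o3"):
            total = sum(getattr(s, f"share_{pol}") for s in self.sectors.values())
            if any(getattr(s, f"share_{pol}") < 0 for s in self.sectors.values()):
                raise ConfigError("sector shares must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{pol} sector shares must sum to 1 (got {total})")
        if not 0.0 <= self.urban_share <= 1.0:
            raise ConfigError("urban share must lie in [0, 1]")
        if not 0.0 <= self.voc_limited_fraction <= 1.0:
            raise ConfigError("voc_limited_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# World
# ---------------------------------------------------------------------------


@dataclass
class World:
    """Static study-world inputs shared by all scenarios."""

    grid: Grid
    population: PopulationGrid
    ages: AgeStructure
    rates: BaselineRates
    region_masks: dict[str, RegionMask]  # 6-region partition
    focal_mask: RegionMask  # GBA-like sub-domain (subset of one region)
    national_mask: RegionMask


# mid age fractions of total population (sum 0.664, adults 25+); bounds +/-3%
_AGE_FRACTIONS = {
    "25-29": 0.085, "30-34": 0.078, "35-39": 0.071, "40-44": 0.081,
    "45-49": 0.086, "50-54": 0.065, "55-59": 0.055, "60-64": 0.050,
    "65-69": 0.035, "70-74": 0.025, "75-79": 0.018, "80+": 0.015,
}

# baseline NCD+LRI mortality per 100,000 per bracket, rising steeply with
# age, with YLL multipliers falling with remaining life expectancy and YLD a
# modest fraction; COPD rates a small old-age-weighted subset. Values are
# synthetic, chosen to be of realistic magnitude.
_MORT_NCD_LRI = [60, 80, 110, 160, 240, 380, 600, 980, 1600, 2700, 4600, 9500]
_YLL_FACTOR = [45, 42, 38, 34, 30, 26, 22, 18, 15, 11, 8.5, 6]
_YLD_FRACTION = 0.15  # of YLL
_MORT_COPD = [1, 2, 3, 6, 12, 25, 55, 120, 260, 480, 760, 1400]
_RATE_REL_BOUND = 0.08


def _age_structure() -> AgeStructure:
    mid = pd.Series(_AGE_FRACTIONS)
    table = pd.DataFrame(
        {"lower": mid * 0.97, "mid": mid, "upper": mid * 1.03}
    )
    table.index.name = "age_bracket"
    return AgeStructure(table)


def _baseline_rates() -> BaselineRates:
    rows = []
    for cause, mort in ((("ncd_lri"), _MORT_NCD_LRI), (("copd"), _MORT_COPD)):
        for b, m, yf in zip(AGE_BRACKETS, mort, _YLL_FACTOR):
            yll = m * yf
            yld = yll * _YLD_FRACTION
            for metric, mid in (("mort", m), ("yll", yll), ("yld", yld)):
                rows.append(
                    {
                        "cause": cause,
                        "age_bracket": b,
                        "metric": metric,
                        "lower": mid * (1 - _RATE_REL_BOUND),
                        "mid": float(mid),
                        "upper": mid * (1 + _RATE_REL_BOUND),
                    }
                )
    return BaselineRates.from_per_100k(pd.DataFrame(rows))


def _region_partition(grid: Grid) -> tuple[dict[str, RegionMask], RegionMask]:
    """2 x 3 block partition plus a 3 x 3-cell focal block in the south-center."""
    names = [
        ["north_west", "north", "north_east"],
        ["south_west", "south_central", "south_east"],
    ]
    masks = {}
    lat_split = grid.n_lat // 2
    lon_thirds = [0, grid.n_lon // 3, 2 * grid.n_lon // 3, grid.n_lon]
    for r in range(2):
        rows = slice(lat_split, grid.n_lat) if r == 0 else slice(0, lat_split)
        for c in range(3):
            w = np.zeros(grid.shape)
            w[rows, lon_thirds[c]:lon_thirds[c + 1]] = 1.0
            masks[names[r][c]] = RegionMask(names[r][c], w)
    # focal block sits inside south_central, near its southern edge
    w = np.zeros(grid.shape)
    i0 = max(0, lat_split // 4)
    j0 = lon_thirds[1] + (lon_thirds[2] - lon_thirds[1]) // 2
    w[i0:i0 + 3, j0:j0 + 3] = 1.0
    return masks, RegionMask("gba", w)


def gen_world(config: SyntheticConfig) -> World:
    """Build the static inputs: grid, population, ages, rates and regions."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(seeds[0])

    lat = np.linspace(
        config.lat_min, config.lat_max, 2 * config.n_lat + 1
    )[1::2]
    lon = np.linspace(
        config.lon_min, config.lon_max, 2 * config.n_lon + 1
    )[1::2]
    grid = Grid(lat, lon)

    # rural field: smoothed positive noise
    rural = gaussian_filter(
        rng.random(grid.shape), sigma=config.rural_smooth_sigma, mode="nearest"
    )
    rural = rural - rural.min() + 0.2
    rural /= rural.sum()

    # urban peaks: Gaussian kernels at random interior cells
    urban = np.zeros(grid.shape)
    ii, jj = np.mgrid[0: grid.n_lat, 0: grid.n_lon]
    margin_i = min(2, max(0, grid.n_lat // 2 - 1))
    margin_j = min(2, max(0, grid.n_lon // 2 - 1))
    for _ in range(config.n_urban_centers):
        ci = rng.integers(margin_i, grid.n_lat - margin_i)
        cj = rng.integers(margin_j, grid.n_lon - margin_j)
        amp = rng.uniform(0.5, 1.5)
        urban += amp * np.exp(
            -((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * config.urban_sigma_cells**2)
        )
    if urban.sum() > 0:
        urban /= urban.sum()

    density = (1 - config.urban_share) * rural + config.urban_share * urban
    counts = density / density.sum() * config.total_population
    population = PopulationGrid(grid, counts)

    region_masks, focal = _region_partition(grid)
    national = RegionMask("china", np.ones(grid.shape))
    return World(
        grid=grid,
        population=population,
        ages=_age_structure(),
        rates=_baseline_rates(),
        region_masks=region_masks,
        focal_mask=focal,
        national_mask=national,
    )


# ---------------------------------------------------------------------------
# Concentrations
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Generated control fields plus exact components for oracle testing.

    ``control[p] = background[p] + sum_k spatial[p][k] x temporal[p][k]
    + noise[p]`` exactly, before clipping at zero; ``clip_count`` records how
    many cell-hours were clipped. ``voc_limited`` is the signed ozone regime
    map (True where precursor cuts raise ozone).
    """

    config: SyntheticConfig
    world: World
    time: pd.DatetimeIndex
    background: dict[str, np.ndarray]  # (nlat, nlon)
    spatial: dict[str, dict[str, np.ndarray]]  # pollutant -> sector -> (nlat, nlon)
    temporal: dict[str, dict[str, np.ndarray]]  # pollutant -> sector -> (T,)
    noise: dict[str, np.ndarray]  # (T, nlat, nlon)
    control: dict[str, ConcentrationField]
    clip_count: dict[str, int]
    voc_limited: np.ndarray  # (nlat, nlon) bool

    def component_hourly(self, pollutant: str, sector: str) -> np.ndarray:
        """Materialize one sector's hourly component."""
        return (
            self.temporal[pollutant][sector][:, None, None]
            * self.spatial[pollutant][sector][None, :, :]
        )


def _pw_mean(values: np.ndarray, pop: PopulationGrid) -> float:
    return float((values * pop.counts).sum() / pop.counts.sum())


def _sector_pattern(spec: SectorSpec, world: World) -> np.ndarray:
    dens = world.population.counts / world.population.counts.sum()
    urbanity = dens / dens.max()
    rural = gaussian_filter(1.0 - urbanity, sigma=1.0, mode="nearest")
    rural = np.clip(rural, 0.05, None)
    if spec.spatial == "urban":
        raw = urbanity + 0.05
    elif spec.spatial == "rural":
        raw = rural
    else:
        raw = 0.5 * (urbanity + 0.05) + 0.5 * rural
    # light smoothing emulates transport/dispersion of sector emissions
    return gaussian_filter(raw, sigma=1.0, mode="nearest")


def gen_concentrations(config: SyntheticConfig, world: World) -> SyntheticTruth:
    """Generate hourly control fields for both pollutants, components retained."""
    time = pd.date_range(
        f"{config.year}-01-01", f"{config.year}-12-31 23:00", freq="h"
    )
    n_hours = len(time)
    hour = time.hour.to_numpy()
    doy = time.dayofyear.to_numpy()
    n_doy = 366 if time[-1].dayofyear == 366 else 365

    seeds = np.random.SeedSequence(config.seed).spawn(4)
    noise_rngs = {
        "pm25": np.random.default_rng(seeds[1]),
        "o3": np.random.default_rng(seeds[2]),
    }

    sectors = list(config.sectors)
    background = {
        "pm25": np.full(world.grid.shape, config.background_pm25),
        "o3": np.full(world.grid.shape, config.background_o3),
    }
    amps = {
        "pm25": (config.diurnal_amp_pm25, config.seasonal_amp_pm25),
        "o3": (config.diurnal_amp_o3, config.seasonal_amp_o3),
    }
    totals = {"pm25": config.sector_total_pm25, "o3": config.sector_total_o3}
    noise_sd = {"pm25": config.noise_sd_pm25, "o3": config.noise_sd_o3}

    spatial: dict[str, dict[str, np.ndarray]] = {"pm25": {}, "o3": {}}
    temporal: dict[str, dict[str, np.ndarray]] = {"pm25": {}, "o3": {}}
    noise: dict[str, np.ndarray] = {}
    control: dict[str, ConcentrationField] = {}
    clip_count: dict[str, int] = {}

    for k, sector in enumerate(sectors):
        spec = config.sectors[sector]
        pattern = _sector_pattern(spec, world)
        for pol in ("pm25", "o3"):
            d_amp, s_amp = amps[pol]
            # ozone peaks in daytime/summer; PM2.5 in morning-evening/winter.
            d_phase = 15.0 if pol == "o3" else 8.0 + k  # hour of diurnal peak
            s_peak = 200.0 if pol == "o3" else 15.0  # day of seasonal peak
            t_mod = (
                1.0
                + d_amp * np.cos(2 * np.pi * (hour - d_phase) / 24.0)
                + s_amp * np.cos(2 * np.pi * (doy - s_peak) / n_doy)
            )
            share = getattr(spec, f"share_{pol}")
            target = share * totals[pol]
            base_pw = _pw_mean(pattern, world.population) * float(t_mod.mean())
            s_field = pattern * (target / base_pw) if base_pw > 0 else pattern * 0.0
            spatial[pol][sector] = s_field
            temporal[pol][sector] = t_mod

    for pol in ("pm25", "o3"):
        rng = noise_rngs[pol]
        rho = config.noise_rho
        innov_sd = noise_sd[pol] * np.sqrt(1 - rho**2)
        e = rng.normal(0.0, innov_sd, size=(n_hours, *world.grid.shape))
        n = np.empty_like(e)
        n[0] = rng.normal(0.0, noise_sd[pol], size=world.grid.shape)
        for t in range(1, n_hours):
            n[t] = rho * n[t - 1] + e[t]
        noise[pol] = n

        total = background[pol][None, :, :] + noise[pol]
        for sector in sectors:
            total = total + (
                temporal[pol][sector][:, None, None]
                * spatial[pol][sector][None, :, :]
            )
        clip_count[pol] = int((total < 0).sum())
        np.clip(total, 0.0, None, out=total)
        control[pol] = ConcentrationField(
            grid=world.grid,
            pollutant=Pollutant(pol),
            values=total,
            time=time,
            scenario_id="control",
        )

    dens = world.population.counts
    threshold = np.quantile(dens, 1.0 - config.voc_limited_fraction)
    voc_limited = dens >= threshold

    return SyntheticTruth(
        config=config,
        world=world,
        time=time,
        background=background,
        spatial=spatial,
        temporal=temporal,
        noise=noise,
        control=control,
        clip_count=clip_count,
        voc_limited=voc_limited,
    )


def _domain_mask(truth: SyntheticTruth, domain: str) -> np.ndarray:
    focal = truth.world.focal_mask.weights
    if domain == "national":
        return np.ones(truth.world.grid.shape)
    if domain == "inside_focal":
        return focal
    return 1.0 - focal


def gen_scenario(
    truth: SyntheticTruth, scenario: ScenarioDef
) -> dict[str, ConcentrationField]:
    """Apply a sector-scaled perturbation to the control fields.

    PM2.5 responds linearly: the scenario removes ``scale`` of the sector
    component inside the domain. Ozone responds with the regime sign for
    precursor sectors (``o3_signed``): the component is subtracted in
    NOx-limited cells and added in VOC-limited cells.
    """
    if scenario.sector not in truth.config.sectors:
        raise ConfigError(f"unknown sector {scenario.sector!r}")
    spec = truth.config.sectors[scenario.sector]
    dom = _domain_mask(truth, scenario.domain)
    out = {}
    for pol in ("pm25", "o3"):
        comp = truth.component_hourly(pol, scenario.sector)
        if pol == "o3" and spec.o3_signed:
            sign = np.where(truth.voc_limited, -1.0, 1.0)
        else:
            sign = 1.0
        values = truth.control[pol].values - scenario.scale * (dom * sign) * comp
        np.clip(values, 0.0, None, out=values)
        out[pol] = ConcentrationField(
            grid=truth.world.grid,
            pollutant=Pollutant(pol),
            values=values,
            time=truth.time,
            scenario_id=scenario.name,
        )
    return out


def gen_stations(
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    pollutant: str = "pm25",
) -> list[StationRecord]:
    """Sample noisy station observations of the control field.

    Stations are placed population-weighted (with replacement, so two
    stations may share a cell); observations are the true cell series times
    (1 + station bias) plus additive noise, with a configured fraction of
    missing hours. Station placement and noise use a sub-stream independent
    of the concentration noise, so changing the station count never perturbs
    the fields.
    """
    config = config or truth.config
    if config.n_stations < 1:
        raise ConfigError("station count must be >= 1")
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(seeds[3])
    world = truth.world
    p = (world.population.counts / world.population.counts.sum()).ravel()
    cells = rng.choice(p.size, size=config.n_stations, p=p, replace=True)
    field_vals = truth.control[pollutant].values
    lat_step = np.diff(world.grid.lat_centers).mean() if world.grid.n_lat > 1 else 1.0
    lon_step = np.diff(world.grid.lon_centers).mean() if world.grid.n_lon > 1 else 1.0
    out = []
    for s, flat in enumerate(cells):
        i, j = divmod(int(flat), world.grid.n_lon)
        lat = world.grid.lat_centers[i] + rng.uniform(-0.3, 0.3) * lat_step
        lon = world.grid.lon_centers[j] + rng.uniform(-0.3, 0.3) * lon_step
        bias = config.station_bias_mean + rng.normal(0.0, config.station_bias_sd)
        obs = field_vals[:, i, j] * (1.0 + bias)
        if config.station_noise_sd > 0:
            obs = obs + rng.normal(0.0, config.station_noise_sd, size=obs.shape)
        obs = np.clip(obs, 0.0, None)
        if config.station_missing_frac > 0:
            missing = rng.random(obs.shape) < config.station_missing_frac
            obs = np.where(missing, np.nan, obs)
        out.append(
            StationRecord(
                station_id=f"st{s:04d}",
                lat=float(lat),
                lon=float(lon),
                series=pd.Series(obs, index=truth.time),
            )
        )
    return out
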