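"""Exposure metrics computed from concentration fields.

Two exposure metrics drive the burden assessment: the per-cell annual-mean
PM2.5 concentration and the 6mDM8h ozone metric — the maximum, over twelve
six-consecutive-calendar-month windows, of the mean of daily-maximum 8-hour
rolling-mean ozone. Population-weighted summaries, scenario differences and
NMBF-based bias adjustment complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InputError
from .grid_io import ConcentrationField, Grid, Pollutant, PopulationGrid, RegionMask
from .utils import round_half_up


class ExposureMetric(str, Enum):
    ANNUAL_MEAN_PM25 = "annual_mean_pm25"
    SIX_M_DM8H_O3 = "6mdm8h_o3"


@dataclass
class ExposureField:
    """Per-cell scalar exposure (ug m-3 for PM2.5, ppb for ozone)."""

    grid: Grid
    pollutant: Pollutant
    metric: ExposureMetric
    values: np.ndarray
    scenario_id: str = "control"

    def __post_init__(self):
        self.pollutant = Pollutant(self.pollutant)
        self.metric = ExposureMetric(self.metric)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("exposure values must be finite and non-negative")
        if self.values.shape != self.grid.shape:
            raise InputError("exposure shape does not match grid")


@dataclass(frozen=True)
class EvaluationBias:
    """Model-vs-observation bias pair (see :mod:`airburden.evaluation`)."""

    nmbf: float
    nmaef: float

    def __post_init__(self):
        if self.nmaef < abs(self.nmbf) * (1 - 1e-12) - 1e-12:
            raise InputError("NMAEF must be >= |NMBF|")


def annual_mean(field: ConcentrationField) -> ExposureField:
    """Per-cell arithmetic mean over all time steps of a PM2.5 field."""
    if field.time is None:
        # already aggregated — pass through
        values = field.values
    else:
        if len(field.time) == 0:
            raise InputError("empty time axis")
        values = field.values.mean(axis=0)
    return ExposureField(
        grid=field.grid,
        pollutant=field.pollutant,
        metric=ExposureMetric.ANNUAL_MEAN_PM25,
        values=values,
        scenario_id=field.scenario_id,
    )


def six_m_dm8h(field: ConcentrationField, wrap: bool = True) -> ExposureField:
    """6mDM8h ozone exposure from a complete hourly calendar year.

    Steps, per cell: (i) 8-h forward rolling means for every start hour
    (windows running past year-end are dropped, not padded); (ii) daily value
    = maximum over the up-to-24 windows starting that day; (iii) candidate
    means of the daily values over 6 consecutive calendar months starting at
    each month (wrapping within the same year when ``wrap`` is true, else
    only the 7 non-wrapping windows); (iv) result = maximum candidate.
    """
    if field.pollutant is not Pollutant.O3:
        raise InputError("6mDM8h is defined for ozone fields")
    if field.time is None:
        raise InputError("6mDM8h requires an hourly field")
    t = field.time
    year = t[0].year
    expected = pd.date_range(f"{year}-01-01", f"{year}-12-31 23:00", freq="h")
    if len(t) != len(expected) or not (t == expected).all():
        raise InputError("6mDM8h requires a complete hourly calendar year")

    v = field.values
    n_hours = v.shape[0]
    n_days = n_hours // 24
    # (i) 8-h forward rolling means, accumulated in the pairwise order of an
    # 8-element np.mean so results are bit-identical to a per-window mean.
    p = [v[k : n_hours - 7 + k] for k in range(8)]
    wmeans = (
        ((p[0] + p[1]) + (p[2] + p[3])) + ((p[4] + p[5]) + (p[6] + p[7]))
    ) / 8.0  # (n_hours - 7, nlat, nlon)
    # (ii) daily maxima; pad the 7 dropped year-end windows with -inf
    padded = np.full((n_days * 24, *field.grid.shape), -np.inf)
    padded[: wmeans.shape[0]] = wmeans
    daily = padded.reshape(n_days, 24, *field.grid.shape).max(axis=1)
    # (iii)/(iv) 6-month candidate means, reduced per cell as 1-D series so
    # the accumulation order matches a direct per-cell computation
    day_month = t[::24].month.to_numpy()
    starts = range(1, 13) if wrap else range(1, 8)
    best = np.full(field.grid.shape, -np.inf)
    n_lat, n_lon = field.grid.shape
    for m in starts:
        members = {(m - 1 + k) % 12 + 1 for k in range(6)}
        sel = np.isin(day_month, list(members))
        sub = daily[sel]
        candidate = np.empty(field.grid.shape)
        for i in range(n_lat):
            for j in range(n_lon):
                candidate[i, j] = np.mean(sub[:, i, j])
        best = np.maximum(best, candidate)
    return ExposureField(
        grid=field.grid,
        pollutant=field.pollutant,
        metric=ExposureMetric.SIX_M_DM8H_O3,
        values=best,
        scenario_id=field.scenario_id,
    )


def population_weighted_mean(
    exposure: ExposureField,
    pop: PopulationGrid,
    mask: RegionMask | None = None,
) -> float:
    """Population-weighted mean exposure over a region.

    Returns ``sum(value * P * w) / sum(P * w)`` with ``w`` the mask weight
    (1 everywhere when no mask is given).
    """
    if exposure.grid != pop.grid:
        raise InputError("exposure and population grids differ")
    w = np.ones(exposure.grid.shape) if mask is None else mask.weights
    weights = pop.counts * w
    denom = weights.sum()
    if denom <= 0:
        raise InputError("zero weighted population: exposure undefined")
    return float((exposure.values * weights).sum() / denom)


def scenario_delta(
    control: ExposureField,
    scenario: ExposureField,
    pop: PopulationGrid,
    mask: RegionMask | None = None,
) -> tuple[float, int]:
    """Population-weighted exposure change of a scenario relative to control.

    Returns ``(absolute_change, percent_change)`` where the absolute change is
    PW(control) − PW(scenario) and the percent change is rounded half-up to
    the nearest integer, matching the reporting convention.
    """
    if control.grid != scenario.grid:
        raise InputError("control and scenario grids differ")
    if control.metric != scenario.metric or control.pollutant != scenario.pollutant:
        raise InputError("control and scenario metrics differ")
    pw_control = population_weighted_mean(control, pop, mask)
    pw_scenario = population_weighted_mean(scenario, pop, mask)
    absolute = pw_control - pw_scenario
    if pw_control == 0:
        raise InputError("percent change undefined: control exposure is zero")
    return absolute, percent_change(pw_control, absolute)


def percent_change(control_value: float, absolute_change: float) -> int:
    """Percent change relative to control, rounded half-up to an integer."""
    return round_half_up(100.0 * absolute_change / control_value)


def bias_adjust(exposure, nmbf: float):
    """Adjust a simulated exposure by a normalized mean bias factor.

    ``adjusted = exposure * (1 - NMBF)``: a positive model bias scales the
    exposure down, a negative bias scales it up. Accepts a scalar or an
    :class:`ExposureField`.
    """
    if nmbf <= -1:
        raise InputError("NMBF must be > -1 for bias adjustment")
    if isinstance(exposure, ExposureField):
        return ExposureField(
            grid=exposure.grid,
            pollutant=exposure.pollutant,
            metric=exposure.metric,
            values=exposure.values * (1.0 - nmbf),
            scenario_id=exposure.scenario_id,
        )
    return float(exposure) * (1.0 - nmbf)
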