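"""Regional aggregation, avoided-burden comparison and summary tables.

Counts are aggregated over cells before any rate is computed (never by
averaging rates), DALY rates are reported per 100,000 of the regional
population, and avoided-burden uncertainty subtracts bound to bound
(lower - lower, upper - upper), matching the simultaneous-envelope
construction of the burden module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .grid_io import PopulationGrid, RegionMask
from .hia import METRICS, VARIANTS, BurdenResult
from .utils import round_half_up, round_to_hundred


@dataclass
class RegionSummary:
    """Aggregated burden and exposure for one region under one scenario.

    ``counts`` is indexed by ``(cause, metric)`` with columns lower/mid/upper.
    """

    region_id: str
    scenario_id: str
    population: float
    counts: pd.DataFrame
    pw_pm25: float | None = None
    pw_o3: float | None = None

    @property
    def rates_per_100k(self) -> pd.DataFrame:
        if self.population <= 0:
            raise InputError(f"region {self.region_id!r} has no population")
        return self.counts / self.population * 100_000.0


@dataclass
class ScenarioComparison:
    """Avoided burden of a scenario relative to control for one region.

    ``avoided`` is indexed by ``(cause, metric)``; per-pollutant terms are
    additive, so the ``combined`` rows are their sums (an ozone term may be
    negative when a scenario raises ozone exposure).
    """

    region_id: str
    scenario_id: str
    avoided: pd.DataFrame
    delta_pm25: tuple[float, int] | None = None
    delta_o3: tuple[float, int] | None = None

    def combined(self, metric: str = "mort") -> pd.Series:
        """Summed avoided burden across causes for one metric."""
        sub = self.avoided.xs(metric, level="metric")
        return sub.sum(axis=0)


def aggregate_burden(
    result: BurdenResult,
    masks,
    pop: PopulationGrid,
    pw_exposures: dict | None = None,
) -> dict[str, RegionSummary]:
    """Aggregate a per-cell burden to regional summaries.

    ``pw_exposures`` optionally maps region_id -> (pw_pm25, pw_o3) to carry
    population-weighted exposures onto the summaries. Empty regions (zero
    weighted population) are skipped with a warning.
    """
    causes = list(result.counts.coords["cause"].values)
    summaries: dict[str, RegionSummary] = {}
    for mask in masks:
        if mask.weights.shape != result.grid.shape:
            raise InputError(f"mask {mask.region_id!r} not on result grid")
        population = float((pop.counts * mask.weights).sum())
        if population <= 0:
            warnings.warn(f"region {mask.region_id!r} is empty; skipped")
            continue
        rows = []
        for cause in causes:
            for metric in METRICS:
                row = {"cause": cause, "metric": metric}
                for variant in VARIANTS:
                    cell_totals = result.total(cause, metric, variant)
                    row[variant] = float((cell_totals * mask.weights).sum())
                rows.append(row)
        counts = pd.DataFrame(rows).set_index(["cause", "metric"])
        pw_pm25 = pw_o3 = None
        if pw_exposures and mask.region_id in pw_exposures:
            pw_pm25, pw_o3 = pw_exposures[mask.region_id]
        summaries[mask.region_id] = RegionSummary(
            region_id=mask.region_id,
            scenario_id=result.scenario_id,
            population=population,
            counts=counts,
            pw_pm25=pw_pm25,
            pw_o3=pw_o3,
        )
    return summaries


def avoided_burden(control: RegionSummary, scenario: RegionSummary) -> ScenarioComparison:
    """Avoided burden = control - scenario, differenced bound to bound."""
    if control.region_id != scenario.region_id:
        raise InputError("region mismatch between control and scenario")
    if not control.counts.index.equals(scenario.counts.index):
        raise InputError("structural mismatch between control and scenario counts")
    avoided = control.counts - scenario.counts
    delta_pm25 = delta_o3 = None
    if control.pw_pm25 is not None and scenario.pw_pm25 is not None:
        d = control.pw_pm25 - scenario.pw_pm25
        delta_pm25 = (d, round_half_up(100 * d / control.pw_pm25))
    if control.pw_o3 is not None and scenario.pw_o3 is not None:
        d = control.pw_o3 - scenario.pw_o3
        delta_o3 = (d, round_half_up(100 * d / control.pw_o3))
    return ScenarioComparison(
        region_id=control.region_id,
        scenario_id=scenario.scenario_id,
        avoided=avoided,
        delta_pm25=delta_pm25,
        delta_o3=delta_o3,
    )


def paper_tables(
    summaries: dict[str, dict[str, RegionSummary]],
    comparisons: dict[str, dict[str, ScenarioComparison]],
) -> pd.DataFrame:
    """Summary table: one row per (region, scenario).

    ``summaries[scenario_id][region_id]`` and
    ``comparisons[scenario_id][region_id]`` follow the pipeline layout.
    Columns report population-weighted exposures, their percent change
    relative to control (half-up integers), and avoided premature deaths
    (combined across pollutants, mid and 95UI, rounded to the nearest 100).
    """
    rows = []
    for scenario_id, per_region in comparisons.items():
        for region_id, cmp_ in per_region.items():
            summ = summaries[scenario_id][region_id]
            combined = cmp_.combined("mort")
            daly = cmp_.combined("daly")
            row = {
                "region": region_id,
                "scenario": scenario_id,
                "population": summ.population,
                "pw_pm25": summ.pw_pm25,
                "pw_o3": summ.pw_o3,
                "pm25_change_pct": cmp_.delta_pm25[1] if cmp_.delta_pm25 else None,
                "o3_change_pct": cmp_.delta_o3[1] if cmp_.delta_o3 else None,
                "avoided_mort_mid": round_to_hundred(combined["mid"]),
                "avoided_mort_lower": round_to_hundred(combined["lower"]),
                "avoided_mort_upper": round_to_hundred(combined["upper"]),
                "avoided_daly_per_100k_mid": daly["mid"] / summ.population * 100_000.0,
            }
            rows.append(row)
    return pd.DataFrame(rows)


def conservation_check(
    partition_summaries: dict[str, RegionSummary],
    national: RegionSummary,
    rtol: float = 1e-9,
) -> bool:
    """True when partition region counts sum to the national counts."""
    total = sum(s.counts for s in partition_summaries.values())
    return bool(np.allclose(total.values, national.counts.values, rtol=rtol, atol=1e-9))
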