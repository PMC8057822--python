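"""Gridded data model and file I/O.

Defines the in-memory containers shared by the whole pipeline — a regular
lat/lon :class:`Grid`, time-resolved :class:`ConcentrationField`,
:class:`PopulationGrid`, :class:`AgeStructure`, :class:`RegionMask` and
:class:`StationRecord` — together with readers/writers for CF-style NetCDF,
GeoJSON region sets and CSV station/age tables.

Conventions: coordinates are cell centers on a regular grid, spatial indexing
is 0-based ``[lat, lon]``, and all arrays are float64. PM2.5 is carried in
ug m-3 and ozone in ppb; readers convert recognised unit strings to these
canonical units and refuse unknown ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
import yaml
from shapely.geometry import shape as _geojson_shape

from .errors import BoundsError, ConfigError, FormatError, GeometryError, InputError

EARTH_RADIUS_KM = 6371.0


class Pollutant(str, Enum):
    PM25 = "pm25"
    O3 = "o3"


#: canonical units per pollutant
CANONICAL_UNITS = {Pollutant.PM25: "ug m-3", Pollutant.O3: "ppb"}

#: accepted unit spellings -> multiplicative factor to the canonical unit
_UNIT_FACTORS = {
    Pollutant.PM25: {
        "ug m-3": 1.0,
        "ug/m3": 1.0,
        "ug m^-3": 1.0,
        "µg m-3": 1.0,
        "microgram m-3": 1.0,
    },
    Pollutant.O3: {"ppb": 1.0, "ppbv": 1.0, "ppm": 1000.0, "ppmv": 1000.0},
}


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _check_strictly_monotonic(x: np.ndarray, name: str) -> None:
    d = np.diff(x)
    if x.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError(f"{name} axis is not strictly monotonic")


@dataclass(frozen=True)
class Grid:
    """Regular latitude/longitude grid defined by its cell centers."""

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_area_km2: np.ndarray | None = None

    def __post_init__(self):
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        _check_strictly_monotonic(lat, "latitude")
        _check_strictly_monotonic(lon, "longitude")
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if self.cell_area_km2 is not None:
            area = _as_float_array(self.cell_area_km2, "cell_area")
            if area.shape != self.shape:
                raise InputError("cell_area shape does not match grid")
            object.__setattr__(self, "cell_area_km2", area)

    @property
    def n_lat(self) -> int:
        return self.lat_centers.size

    @property
    def n_lon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def _edges(self, centers: np.ndarray) -> np.ndarray:
        mid = 0.5 * (centers[1:] + centers[:-1])
        first = centers[0] - (mid[0] - centers[0]) if centers.size > 1 else centers[0] - 0.5
        last = centers[-1] + (centers[-1] - mid[-1]) if centers.size > 1 else centers[-1] + 0.5
        return np.concatenate([[first], mid, [last]])

    @property
    def lat_edges(self) -> np.ndarray:
        return self._edges(self.lat_centers)

    @property
    def lon_edges(self) -> np.ndarray:
        return self._edges(self.lon_centers)

    def contains(self, lat: float, lon: float) -> bool:
        la, lo = self.lat_edges, self.lon_edges
        return (min(la[0], la[-1]) <= lat <= max(la[0], la[-1])) and (
            min(lo[0], lo[-1]) <= lon <= max(lo[0], lo[-1])
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Grid)
            and np.array_equal(self.lat_centers, other.lat_centers)
            and np.array_equal(self.lon_centers, other.lon_centers)
        )


@dataclass
class ConcentrationField:
    """Time-resolved (or pre-aggregated annual) concentrations for one scenario.

    ``values`` has shape ``(n_time, n_lat, n_lon)`` when a ``time`` axis is
    present (hourly, uniform 1-h step) and ``(n_lat, n_lon)`` for an annual
    field (``time is None``).
    """

    grid: Grid
    pollutant: Pollutant
    values: np.ndarray
    time: pd.DatetimeIndex | None = None
    scenario_id: str = "control"

    def __post_init__(self):
        self.pollutant = Pollutant(self.pollutant)
        self.values = _as_float_array(self.values, "concentration values")
        if np.any(self.values < 0):
            raise InputError("concentration values must be non-negative")
        if self.time is None:
            if self.values.shape != self.grid.shape:
                raise InputError("annual field shape does not match grid")
        else:
            self.time = pd.DatetimeIndex(self.time)
            if self.values.shape != (len(self.time), *self.grid.shape):
                raise InputError("field shape does not match (time, lat, lon)")
            if len(self.time) > 1:
                steps = np.diff(self.time.asi8)
                if np.any(steps <= 0):
                    raise InputError("time axis must be strictly increasing")
                if not np.all(steps == 3_600_000_000_000):
                    raise InputError("time axis must have a uniform 1-hour step")

    @property
    def is_hourly(self) -> bool:
        return self.time is not None


@dataclass
class PopulationGrid:
    """Person counts per grid cell."""

    grid: Grid
    counts: np.ndarray

    def __post_init__(self):
        self.counts = _as_float_array(self.counts, "population counts")
        if np.any(self.counts < 0):
            raise InputError("population counts must be non-negative")
        if self.counts.shape != self.grid.shape:
            raise InputError("population shape does not match grid")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class RegionMask:
    """Per-cell membership (boolean or fractional weight in [0, 1])."""

    region_id: str
    weights: np.ndarray

    def __post_init__(self):
        self.weights = _as_float_array(self.weights, "mask weights")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise InputError(f"mask weights for {self.region_id!r} not in [0, 1]")


def validate_partition(masks: Iterable[RegionMask], tol: float = 1e-9) -> None:
    """Check that a set of masks covers every cell with weights summing to 1."""
    masks = list(masks)
    total = sum(m.weights for m in masks)
    if not np.allclose(total, 1.0, atol=tol, rtol=0):
        raise InputError("masks do not form a partition (weights do not sum to 1)")


@dataclass
class StationRecord:
    """One monitoring site: coordinates plus a time-stamped observation series.

    Missing observations are NaN in ``series`` and excluded pairwise during
    evaluation.
    """

    station_id: str
    lat: float
    lon: float
    series: pd.Series

    def annual_mean(self) -> float:
        return float(self.series.mean(skipna=True))


@dataclass
class AgeStructure:
    """National age-bracket fractions for adults 25+ with lower/mid/upper variants.

    ``table`` is indexed by bracket label (``25-29`` ... ``80+``) with columns
    ``lower``, ``mid``, ``upper`` holding the fraction of total population.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        missing = {"lower", "mid", "upper"} - set(t.columns)
        if missing:
            raise ConfigError(f"age structure missing columns: {sorted(missing)}")
        if (t[["lower", "mid", "upper"]] < 0).any().any():
            raise ConfigError("age fractions must be non-negative")
        if not ((t["lower"] <= t["mid"]).all() and (t["mid"] <= t["upper"]).all()):
            raise ConfigError("age fractions must satisfy lower <= mid <= upper")
        if t["mid"].sum() > 1 + 1e-9:
            raise ConfigError("mid age fractions exceed the total population share")

    @property
    def brackets(self) -> list[str]:
        return list(self.table.index)

    def fractions(self, variant: str = "mid") -> np.ndarray:
        return self.table[variant].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.rename_axis("age_bracket").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AgeStructure":
        return cls(pd.read_csv(path, index_col="age_bracket"))


@dataclass
class RunConfig:
    """Plumbing configuration for a CLI run."""

    pollutants: tuple[str, ...] = ("pm25", "o3")
    counterfactual_pm25: float = 2.4
    counterfactual_o3: float = 35.7
    risk_parameter_path: str | None = None
    rate_table_path: str | None = None
    scenarios: tuple[str, ...] = ()
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        if self.counterfactual_pm25 <= 0 or self.counterfactual_o3 <= 0:
            raise ConfigError("counterfactual exposure levels must be positive")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pollutants", "scenarios"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style attributes; scipy backend, classic format)
# ---------------------------------------------------------------------------

_TIME_ENCODING = {"units": "hours since 1990-01-01 00:00:00", "dtype": "float64"}


def write_concentration_field(fld: ConcentrationField, path) -> None:
    dims = ("lat", "lon") if fld.time is None else ("time", "lat", "lon")
    coords = {"lat": fld.grid.lat_centers, "lon": fld.grid.lon_centers}
    if fld.time is not None:
        coords["time"] = fld.time
    da = xr.DataArray(fld.values, dims=dims, coords=coords, name=fld.pollutant.value)
    da.attrs["units"] = CANONICAL_UNITS[fld.pollutant]
    da.attrs["scenario_id"] = fld.scenario_id
    ds = da.to_dataset()
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    enc = {"time": _TIME_ENCODING} if fld.time is not None else None
    ds.to_netcdf(path, engine="scipy", encoding=enc)


def read_concentration_field(path, pollutant: Pollutant | str) -> ConcentrationField:
    """Read a concentration field, mapping declared units to canonical units."""
    pollutant = Pollutant(pollutant)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with xr.open_dataset(path, engine="scipy") as ds:
        if pollutant.value not in ds:
            raise FormatError(f"missing variable {pollutant.value!r} in {path.name}")
        for axis in ("lat", "lon"):
            if axis not in ds.coords and axis not in ds.variables:
                raise FormatError(f"missing coordinate variable {axis!r} in {path.name}")
        da = ds[pollutant.value]
        units = str(da.attrs.get("units", "")).strip()
        if not units:
            raise FormatError(f"variable {pollutant.value!r} lacks a 'units' attribute")
        factors = _UNIT_FACTORS[pollutant]
        if units not in factors:
            raise FormatError(
                f"unknown units attribute {units!r} for {pollutant.value!r}"
            )
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        _check_strictly_monotonic(lat, "latitude")
        _check_strictly_monotonic(lon, "longitude")
        values = da.values.astype(float) * factors[units]
        time = pd.DatetimeIndex(ds["time"].values) if "time" in da.dims else None
        scenario_id = str(da.attrs.get("scenario_id", "control"))
    return ConcentrationField(
        grid=Grid(lat, lon),
        pollutant=pollutant,
        values=values,
        time=time,
        scenario_id=scenario_id,
    )


def write_population(pop: PopulationGrid, path) -> None:
    da = xr.DataArray(
        pop.counts,
        dims=("lat", "lon"),
        coords={"lat": pop.grid.lat_centers, "lon": pop.grid.lon_centers},
        name="population",
        attrs={"units": "persons"},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_population(path) -> PopulationGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        if "population" not in ds:
            raise FormatError(f"missing variable 'population' in {Path(path).name}")
        lat = np.asarray(ds["lat"].values, dtype=float)
        lon = np.asarray(ds["lon"].values, dtype=float)
        counts = ds["population"].values.astype(float)
    return PopulationGrid(Grid(lat, lon), counts)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass
class RegionFeature:
    region_id: str
    geometry: shapely.Geometry


def read_regions_geojson(path) -> list[RegionFeature]:
    """Read a GeoJSON FeatureCollection of region polygons.

    The region identifier is taken from ``properties.region_id`` (fallbacks:
    ``properties.name``, the feature ``id``, or the feature index).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        rid = props.get("region_id") or props.get("name") or feat.get("id") or str(i)
        out.append(RegionFeature(str(rid), _geojson_shape(feat["geometry"])))
    return out


def write_regions_geojson(features: Sequence[RegionFeature], path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": f.region_id},
                "geometry": json.loads(shapely.to_geojson(f.geometry)),
            }
            for f in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def rasterize_regions(
    features: Sequence[RegionFeature], grid: Grid, method: str = "centers"
) -> list[RegionMask]:
    """Rasterize polygon features onto the grid.

    ``method="centers"`` (default) assigns membership 1 when the cell center is
    strictly inside the polygon; ``method="area"`` assigns the fractional
    planar (degree-space) overlap of the cell rectangle with the polygon.
    """
    if method not in ("centers", "area"):
        raise ConfigError(f"unknown rasterization method {method!r}")
    lon2d, lat2d = np.meshgrid(grid.lon_centers, grid.lat_centers)
    masks = []
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    for feat in features:
        geom = feat.geometry
        if not geom.is_valid:
            raise GeometryError(f"invalid geometry for feature {feat.region_id!r}")
        if method == "centers":
            inside = shapely.contains_xy(geom, lon2d.ravel(), lat2d.ravel())
            w = inside.reshape(grid.shape).astype(float)
        else:
            w = np.zeros(grid.shape)
            for i in range(grid.n_lat):
                for j in range(grid.n_lon):
                    cell = shapely.box(
                        min(lon_e[j], lon_e[j + 1]),
                        min(lat_e[i], lat_e[i + 1]),
                        max(lon_e[j], lon_e[j + 1]),
                        max(lat_e[i], lat_e[i + 1]),
                    )
                    w[i, j] = geom.intersection(cell).area / cell.area
        masks.append(RegionMask(feat.region_id, w))
    return masks


# ---------------------------------------------------------------------------
# Station matching
# ---------------------------------------------------------------------------


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def nearest_cell(lat: float, lon: float, grid: Grid) -> tuple[int, int]:
    """Index of the cell whose center is nearest (great circle) to the point.

    Ties are broken toward the lower ``(lat, lon)`` index. Points outside the
    grid's outer cell edges raise :class:`BoundsError`.
    """
    if not grid.contains(lat, lon):
        raise BoundsError(f"point ({lat}, {lon}) outside grid bounds")
    lon2d, lat2d = np.meshgrid(grid.lon_centers, grid.lat_centers)
    d = great_circle_km(lat, lon, lat2d, lon2d)
    flat = int(np.argmin(d))  # argmin returns the first minimum -> lower index
    return flat // grid.n_lon, flat % grid.n_lon


# ---------------------------------------------------------------------------
# Station CSV I/O
# ---------------------------------------------------------------------------


def write_stations_csv(stations: Sequence[StationRecord], path) -> None:
    frames = []
    for s in stations:
        frames.append(
            pd.DataFrame(
                {
                    "station_id": s.station_id,
                    "lat": s.lat,
                    "lon": s.lon,
                    "timestamp": s.series.index,
                    "value": s.series.values,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_stations_csv(path) -> list[StationRecord]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"station_id", "lat", "lon", "timestamp", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"station table missing columns: {sorted(missing)}")
    out = []
    for sid, g in df.groupby("station_id", sort=False):
        series = pd.Series(
            g["value"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(g["timestamp"].to_numpy()),
        )
        out.append(
            StationRecord(str(sid), float(g["lat"].iloc[0]), float(g["lon"].iloc[0]), series)
        )
    return out
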