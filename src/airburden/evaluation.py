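"""Model evaluation against station observations.

Skill is measured with the normalized mean bias factor (NMBF) and the
normalized mean absolute error factor (NMAEF) of Yu et al. (2006). Both are
symmetric, scale-invariant factors with a piecewise denominator:

    mean(M) >= mean(O):  NMBF = (SM - SO) / SO,   NMAEF = S|M-O| / SO
    mean(M) <  mean(O):  NMBF = (SM - SO) / SM,   NMAEF = S|M-O| / SM

so that a model overestimating by a factor F gives NMBF = F - 1 and an
underestimate by the same factor gives NMBF = -(F - 1). The default pairing
compares station annual means against the model annual exposure at the
nearest grid cell; an hourly mode pairs individual timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .exposure import EvaluationBias, ExposureField
from .grid_io import ConcentrationField, StationRecord, nearest_cell
from .errors import BoundsError


@dataclass
class PairedSample:
    """Matched model/observation value pairs with missing pairs removed."""

    model: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.model, dtype=float)
        o = np.asarray(self.observed, dtype=float)
        if m.shape != o.shape:
            raise InputError("model and observed sequences differ in length")
        keep = np.isfinite(m) & np.isfinite(o)
        self.model, self.observed = m[keep], o[keep]
        if self.n < 1:
            raise InputError("empty paired sample")

    @property
    def n(self) -> int:
        return self.model.size


def pair_stations(
    exposure: ExposureField, stations: list[StationRecord]
) -> PairedSample:
    """Pair station annual-mean observations with the model exposure field.

    Each station is matched to its nearest grid cell; stations outside the
    grid bounds are skipped. Raises when no station falls inside the grid.
    """
    model_vals, obs_vals = [], []
    for s in stations:
        try:
            i, j = nearest_cell(s.lat, s.lon, exposure.grid)
        except BoundsError:
            continue
        model_vals.append(exposure.values[i, j])
        obs_vals.append(s.annual_mean())
    if not model_vals:
        raise InputError("no stations inside grid bounds")
    return PairedSample(np.array(model_vals), np.array(obs_vals))


def pair_stations_hourly(
    field: ConcentrationField, stations: list[StationRecord]
) -> PairedSample:
    """Pair individual hourly values (optional mode).

    Observation timestamps absent from the model time axis, and missing
    (NaN) observations, are excluded pairwise.
    """
    if field.time is None:
        raise InputError("hourly pairing requires an hourly model field")
    index = {ts: k for k, ts in enumerate(field.time)}
    model_vals, obs_vals = [], []
    for s in stations:
        try:
            i, j = nearest_cell(s.lat, s.lon, field.grid)
        except BoundsError:
            continue
        for ts, val in s.series.items():
            k = index.get(ts)
            if k is not None:
                model_vals.append(field.values[k, i, j])
                obs_vals.append(val)
    if not model_vals:
        raise InputError("no stations inside grid bounds")
    return PairedSample(np.array(model_vals), np.array(obs_vals))


def _sums(sample: PairedSample) -> tuple[float, float]:
    sm = float(sample.model.sum())
    so = float(sample.observed.sum())
    if sm <= 0 or so <= 0:
        raise InputError("NMBF/NMAEF undefined for non-positive sums")
    return sm, so


def nmbf(sample: PairedSample) -> float:
    """Normalized mean bias factor."""
    sm, so = _sums(sample)
    return (sm - so) / so if sm >= so else (sm - so) / sm


def nmaef(sample: PairedSample) -> float:
    """Normalized mean absolute error factor."""
    sm, so = _sums(sample)
    sad = float(np.abs(sample.model - sample.observed).sum())
    return sad / so if sm >= so else sad / sm


def evaluate(sample: PairedSample) -> EvaluationBias:
    """Convenience wrapper returning both factors as an :class:`EvaluationBias`."""
    return EvaluationBias(nmbf=nmbf(sample), nmaef=nmaef(sample))
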