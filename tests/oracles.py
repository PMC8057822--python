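"""Independent brute-force oracles used by the test suite.

Deliberately written with explicit loops and elementary operations, not
sharing code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def six_m_dm8h_brute(values: np.ndarray, time, wrap: bool = True) -> np.ndarray:
    """Loop-based 6mDM8h: 8-h window means -> daily max -> 6-month means -> max.

    ``values`` is (n_hours, n_lat, n_lon) over one complete calendar year.
    """
    n_hours, n_lat, n_lon = values.shape
    n_days = n_hours // 24
    day_month = [time[d * 24].month for d in range(n_days)]
    out = np.empty((n_lat, n_lon))
    starts = range(1, 13) if wrap else range(1, 8)
    for i in range(n_lat):
        for j in range(n_lon):
            series = values[:, i, j]
            daily = []
            for d in range(n_days):
                best = -math.inf
                for h0 in range(d * 24, d * 24 + 24):
                    if h0 + 8 <= n_hours:  # drop windows past year-end
                        m = float(np.mean(series[h0 : h0 + 8]))
                        if m > best:
                            best = m
                daily.append(best)
            daily = np.array(daily)
            best_candidate = -math.inf
            for m0 in starts:
                months = {(m0 - 1 + k) % 12 + 1 for k in range(6)}
                sel = np.array([dm in months for dm in day_month])
                candidate = float(np.mean(daily[sel]))
                if candidate > best_candidate:
                    best_candidate = candidate
            out[i, j] = best_candidate
    return out


def nearest_cell_brute(lat, lon, lat_centers, lon_centers):
    """Exhaustive great-circle minimization, first minimum wins."""
    best = None
    best_d = math.inf
    for i, la in enumerate(lat_centers):
        for j, lo in enumerate(lon_centers):
            p1, p2 = math.radians(lat), math.radians(la)
            dphi = p2 - p1
            dlam = math.radians(lo) - math.radians(lon)
            a = (
                math.sin(dphi / 2) ** 2
                + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
            )
            d = 2 * 6371.0 * math.asin(math.sqrt(min(1.0, a)))
            if d < best_d - 1e-12:
                best_d = d
                best = (i, j)
    return best


def gemm_rr_scalar(z, theta, alpha, mu, nu):
    """Direct scalar evaluation of the GEMM hazard function."""
    if z <= 0:
        return 1.0
    weight = 1.0 / (1.0 + math.exp((mu - z) / nu))
    return math.exp(theta * math.log(1.0 + z / alpha) * weight)
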