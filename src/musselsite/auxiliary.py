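"""Auxiliary decision-support layers: accessibility, maximum wave, port distance.

These layers do not mask the suitability product; they inform operational
decisions (safe working limits for service vessels, line survival, and
steaming distance to the nearest port).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (KM_PER_NM, GridSpec, RasterLayer, TimeSeriesStack,
                   VectorSet, haversine_km)


@dataclass(frozen=True)
class AccessibilityParams:
    wave_limit: float = 1.5          # m significant wave height, strict "under"
    max_wave_limit: float = 6.0      # m record maximum
    port_distances_nm: tuple = (25.0, 55.0)

    def __post_init__(self):
        if self.wave_limit <= 0 or self.max_wave_limit <= 0:
            raise ValueError("wave limits must be positive")
        if any(d <= 0 for d in self.port_distances_nm):
            raise ValueError("port distance thresholds must be positive")


def accessibility(waves: TimeSeriesStack, limit: float = 1.5) -> RasterLayer:
    """Percent of valid time steps with wave height strictly under ``limit``.

    100% means the site is accessible all the time; ties at exactly the
    limit count as inaccessible.
    """
    v = waves.values
    if np.nanmin(v, initial=0.0) < 0:
        raise ValueError("wave heights must be non-negative")
    valid = np.isfinite(v)
    nvalid = valid.sum(axis=0)
    nok = (valid & (v < limit)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        pct = np.where(nvalid > 0, 100.0 * nok / np.maximum(nvalid, 1), np.nan)
    return RasterLayer(waves.grid, pct, variable="accessibility", units="%")


def max_wave(waves: TimeSeriesStack, limit: float = 6.0
             ) -> tuple[RasterLayer, RasterLayer]:
    """Per-cell record maximum wave height and its under-limit flag layer."""
    v = np.where(np.isfinite(waves.values), waves.values, -np.inf)
    mx = v.max(axis=0)
    mx = np.where(np.isfinite(mx), mx, np.nan)
    flag = np.isfinite(mx) & (mx < limit)
    return (RasterLayer(waves.grid, mx, variable="max_wave", units="m"),
            RasterLayer(waves.grid, flag.astype(float), variable="max_wave_ok", units=""))


def distance_to_port(grid: GridSpec, ports: VectorSet,
                     thresholds_nm: tuple = (25.0, 55.0)
                     ) -> tuple[RasterLayer, dict[float, RasterLayer]]:
    """Haversine distance (nautical miles) from each cell center to the nearest port.

    Returns the distance layer plus one Boolean layer per threshold
    (True where the distance is within the threshold).
    """
    pts = [f.geometry for f in ports if f.geometry.geom_type == "Point"]
    if not pts:
        raise ValueError("port set contains no point features")
    lat_grid, lon_grid = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    dist = np.full(grid.shape, np.inf)
    for p in pts:
        d = haversine_km(lat_grid, lon_grid, p.y, p.x)
        dist = np.minimum(dist, d)
    dist_nm = dist / KM_PER_NM
    layer = RasterLayer(grid, dist_nm, variable="port_distance", units="nm")
    masks = {
        float(t): RasterLayer(grid, (dist_nm <= t).astype(float),
                              variable=f"within_{t:g}nm", units="")
        for t in thresholds_nm
    }
    return layer, masks
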