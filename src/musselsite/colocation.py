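"""Co-location ranking: zonal statistics over wind-farm polygons.

Each farm polygon is summarized by the mean of the raster cells whose
centers fall inside it (nearest-cell fallback for sub-cell polygons), and
farms are ranked by mean suitability index, ties broken by accessibility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely

from .grid import RasterLayer, VectorSet, spherical_polygon_area_km2

#: Ranking-report column order.
REPORT_COLUMNS = ["rank", "id", "name", "status", "si", "si_change_2050_pct",
                  "area_km2", "port_distance_nm", "accessibility_pct"]


def zonal_mean(raster: RasterLayer, farms: VectorSet) -> pd.Series:
    """Mean raster value over cell centers inside each farm polygon.

    Missing cells are excluded from the mean.  If no cell center falls
    inside a polygon, the value at the cell center nearest the polygon
    centroid is used instead.
    """
    if raster.values.size == 0:
        raise ValueError("empty raster")
    grid = raster.grid
    lat_grid, lon_grid = np.meshgrid(grid.lats, grid.lons, indexing="ij")
    points = shapely.points(lon_grid.ravel(), lat_grid.ravel())
    tree = shapely.STRtree(points)
    out = {}
    flat = raster.values.ravel()
    for f in farms:
        inside = tree.query(f.geometry, predicate="covers")
        if len(inside) == 0:
            c = f.geometry.centroid
            j = int(np.clip(round((c.x - grid.lon_min) / grid.resolution - 0.5),
                            0, grid.nlon - 1))
            i = int(np.clip(round((c.y - grid.lat_min) / grid.resolution - 0.5),
                            0, grid.nlat - 1))
            out[f.id] = float(raster.values[i, j])
            continue
        vals = flat[inside]
        vals = vals[np.isfinite(vals)]
        out[f.id] = float(vals.mean()) if len(vals) else np.nan
    return pd.Series(out, name=raster.variable or "value")


def rank_farms(records: pd.DataFrame) -> pd.DataFrame:
    """Order farms by descending SI, then descending accessibility, then id.

    Records with missing SI sort last and are flagged in ``unrankable``.
    """
    df = records.copy()
    if len(df) == 0:
        df["unrankable"] = pd.Series(dtype=bool)
        df.insert(0, "rank", pd.Series(dtype=int))
        return df
    df["unrankable"] = ~np.isfinite(df["si"].astype(float))
    df = df.sort_values(
        by=["unrankable", "si", "accessibility_pct", "id"],
        ascending=[True, False, False, True],
        kind="mergesort",  # stable → deterministic
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def farm_report(farms: VectorSet, si: RasterLayer, si_change: RasterLayer,
                accessibility: RasterLayer, port_distance: RasterLayer
                ) -> pd.DataFrame:
    """One ranked row per farm with SI, ΔSI(2050) %, area, distance, accessibility."""
    tables = {
        "si": zonal_mean(si, farms),
        "si_change_2050_pct": zonal_mean(si_change, farms),
        "accessibility_pct": zonal_mean(accessibility, farms),
        "port_distance_nm": zonal_mean(port_distance, farms),
    }
    rows = []
    for f in farms:
        rows.append({
            "id": f.id,
            "name": f.name,
            "status": f.attributes.get("status", ""),
            "area_km2": spherical_polygon_area_km2(f.geometry),
            **{k: v[f.id] for k, v in tables.items()},
        })
    if not rows:
        return pd.DataFrame(columns=REPORT_COLUMNS + ["unrankable"])
    ranked = rank_farms(pd.DataFrame(rows))
    return ranked[REPORT_COLUMNS + ["unrankable"]]
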