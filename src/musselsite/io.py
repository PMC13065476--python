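"""Readers and writers for the standard formats the pipeline touches.

Gridded data travel as classic NetCDF (dimensions ``time``/``lat``/``lon``,
CF-style attributes), vector features as GeoJSON, tables as UTF-8 CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .grid import Feature, GridSpec, RasterLayer, TimeSeriesStack, VectorSet


class FormatError(ValueError):
    """A file does not conform to the expected standard layout."""


def _grid_from_coords(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    if len(lats) < 1 or len(lons) < 1:
        raise FormatError("empty lat/lon coordinate axes")
    res_candidates = []
    for axis in (lats, lons):
        if len(axis) > 1:
            steps = np.diff(axis)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise FormatError("coordinate axes must be uniformly spaced")
            res_candidates.append(abs(steps[0]))
    if not res_candidates:
        raise FormatError("cannot infer resolution from single-cell axes")
    res = res_candidates[0]
    if len(res_candidates) == 2 and not np.isclose(res_candidates[0], res_candidates[1]):
        raise FormatError("lat and lon spacing differ; cells must be square")
    return GridSpec(
        lon_min=float(lons.min() - res / 2), lon_max=float(lons.max() + res / 2),
        lat_min=float(lats.min() - res / 2), lat_max=float(lats.max() + res / 2),
        resolution=float(res),
    )


def _to_dataset(obj) -> xr.Dataset:
    grid = obj.grid
    attrs = {"units": obj.units, **obj.attrs}
    if isinstance(obj, RasterLayer):
        da = xr.DataArray(obj.values, dims=("lat", "lon"),
                          coords={"lat": grid.lats, "lon": grid.lons}, attrs=attrs)
    else:
        da = xr.DataArray(obj.values, dims=("time", "lat", "lon"),
                          coords={"time": obj.times, "lat": grid.lats, "lon": grid.lons},
                          attrs=attrs)
    name = obj.variable or "field"
    ds = da.to_dataset(name=name)
    ds.attrs["resolution_deg"] = grid.resolution
    if isinstance(obj, TimeSeriesStack):
        ds.attrs["cadence"] = obj.cadence
    return ds


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    _to_dataset(layer).to_netcdf(path, engine="scipy")


def write_stack(stack: TimeSeriesStack, path: str | Path) -> None:
    _to_dataset(stack).to_netcdf(path, engine="scipy")


def _single_var(ds: xr.Dataset) -> xr.DataArray:
    names = [v for v in ds.data_vars]
    if len(names) != 1:
        raise FormatError(f"expected exactly one data variable, found {names}")
    return ds[names[0]]


def read_raster(path: str | Path) -> RasterLayer:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = _single_var(ds)
        if set(da.dims) != {"lat", "lon"}:
            raise FormatError(f"raster must have dims (lat, lon), got {da.dims}")
        da = da.transpose("lat", "lon")
        grid = _grid_from_coords(da["lat"].values, da["lon"].values)
        return RasterLayer(grid, da.values.astype(float), str(da.name),
                           str(da.attrs.get("units", "")),
                           {k: v for k, v in da.attrs.items() if k != "units"})


def read_stack(path: str | Path) -> TimeSeriesStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        da = _single_var(ds)
        if set(da.dims) != {"time", "lat", "lon"}:
            raise FormatError(f"stack must have dims (time, lat, lon), got {da.dims}")
        da = da.transpose("time", "lat", "lon")
        grid = _grid_from_coords(da["lat"].values, da["lon"].values)
        cadence = ds.attrs.get("cadence")
        if cadence is None:
            raise FormatError("stack file is missing the 'cadence' attribute")
        return TimeSeriesStack(grid, pd.DatetimeIndex(da["time"].values), cadence,
                               da.values.astype(float), str(da.name),
                               str(da.attrs.get("units", "")),
                               {k: v for k, v in da.attrs.items() if k != "units"})


# ---------------------------------------------------------------------------
# GeoJSON vectors

def write_vectors(vectors: VectorSet, path: str | Path) -> None:
    features = []
    for f in vectors:
        features.append({
            "type": "Feature",
            "id": f.id,
            "properties": {"name": f.name, **f.attributes},
            "geometry": mapping(f.geometry),
        })
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_vectors(path: str | Path) -> VectorSet:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    if payload.get("type") != "FeatureCollection":
        raise FormatError("GeoJSON root must be a FeatureCollection ('type' field)")
    feats = []
    seen = set()
    for i, f in enumerate(payload.get("features", [])):
        if f.get("geometry") is None:
            raise FormatError(f"feature {i} has no 'geometry'")
        fid = str(f.get("id", f.get("properties", {}).get("id", i)))
        if fid in seen:
            raise FormatError(f"duplicate feature id {fid!r}")
        seen.add(fid)
        props = dict(f.get("properties") or {})
        name = props.pop("name", fid)
        feats.append(Feature(fid, name, shape(f["geometry"]), props))
    return VectorSet(feats)


# ---------------------------------------------------------------------------
# CSV tables

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
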