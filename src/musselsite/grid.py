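"""Georeferenced grid model: grids, layers, stacks, areas and regridding.

All grids are geographic (lon/lat degrees), cell-center registered, with
latitude ascending south→north and longitude in [−180, 180).  Missing data
are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0
KM_PER_NM = 1.852

Cadence = Literal["hourly", "3hourly", "daily", "monthly", "decadal"]

#: expected median step for each cadence, as a pandas frequency check window
_CADENCE_STEP = {
    "hourly": (pd.Timedelta("1h"), pd.Timedelta("1h")),
    "3hourly": (pd.Timedelta("3h"), pd.Timedelta("3h")),
    "daily": (pd.Timedelta("1d"), pd.Timedelta("1d")),
    "monthly": (pd.Timedelta("28d"), pd.Timedelta("31d")),
    "decadal": (pd.Timedelta("3650d"), pd.Timedelta("3660d")),
}


class GridError(ValueError):
    """Grid geometry or alignment problem."""


@dataclass(frozen=True)
class GridSpec:
    """A regular geographic grid with square cells and cell-center registration."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise GridError("latitude bounds must satisfy -90 <= lat_min < lat_max <= 90")
        if not (-180 <= self.lon_min < self.lon_max <= 180):
            raise GridError("longitude bounds must lie in [-180, 180]")
        for name, extent in (("lon", self.lon_max - self.lon_min),
                             ("lat", self.lat_max - self.lat_min)):
            n = extent / self.resolution
            if abs(n - round(n)) > 1e-8 * max(1.0, abs(n)):
                raise GridError(
                    f"{name} extent {extent} is not an integer multiple of "
                    f"resolution {self.resolution}"
                )

    @property
    def nlon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def nlat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, ascending."""
        return self.lon_min + (np.arange(self.nlon) + 0.5) * self.resolution

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, ascending (south → north)."""
        return self.lat_min + (np.arange(self.nlat) + 0.5) * self.resolution

    def contains(self, other: "GridSpec") -> bool:
        eps = 1e-9
        return (self.lon_min <= other.lon_min + eps and self.lon_max >= other.lon_max - eps
                and self.lat_min <= other.lat_min + eps and self.lat_max >= other.lat_max - eps)

    def overlaps(self, other: "GridSpec") -> bool:
        return (self.lon_min < other.lon_max and other.lon_min < self.lon_max
                and self.lat_min < other.lat_max and other.lat_min < self.lat_max)


def make_grid(bounds: Sequence[float], resolution: float) -> GridSpec:
    """Build a :class:`GridSpec` from ``[lon_min, lon_max, lat_min, lat_max]``."""
    lon_min, lon_max, lat_min, lat_max = map(float, bounds)
    return GridSpec(lon_min, lon_max, lat_min, lat_max, float(resolution))


@dataclass
class RasterLayer:
    """A single 2-D field on a grid (lat-major, NaN = missing)."""

    grid: GridSpec
    values: np.ndarray
    variable: str = ""
    units: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def copy_with(self, values: np.ndarray, **kw) -> "RasterLayer":
        out = RasterLayer(self.grid, values, self.variable, self.units, dict(self.attrs))
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class TimeSeriesStack:
    """A (time × lat × lon) stack of one variable at a declared cadence."""

    grid: GridSpec
    times: pd.DatetimeIndex
    cadence: Cadence
    values: np.ndarray
    variable: str = ""
    units: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise GridError(
                f"stack shape {self.values.shape} does not match (time, {self.grid.shape})"
            )
        if len(self.times) != self.values.shape[0]:
            raise GridError("time axis length mismatch")
        if len(self.times) > 1:
            steps = np.diff(self.times.values)
            if not (steps > np.timedelta64(0, "s")).all():
                raise GridError("timestamps must be strictly increasing")
            lo, hi = _CADENCE_STEP[self.cadence]
            med = pd.Timedelta(np.median(steps))
            if not (lo <= med <= hi):
                raise GridError(
                    f"median step {med} inconsistent with cadence {self.cadence!r}"
                )

    def __len__(self) -> int:
        return len(self.times)

    def slice_layer(self, i: int) -> RasterLayer:
        return RasterLayer(self.grid, self.values[i], self.variable, self.units)


@dataclass
class Feature:
    """One vector feature: a wind-farm polygon or a port point."""

    id: str
    name: str
    geometry: BaseGeometry
    attributes: dict = field(default_factory=dict)


@dataclass
class VectorSet:
    """A small collection of vector features with unique ids."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")
        for f in self.features:
            if f.geometry.geom_type == "Polygon" and not f.geometry.is_valid:
                raise ValueError(f"polygon {f.id!r} is invalid (self-intersecting?)")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


# ---------------------------------------------------------------------------
# areas

def cell_areas(grid: GridSpec) -> RasterLayer:
    """Spherical area of every cell in km².

    A = R² · Δλ · (sin φ_top − sin φ_bot) with R = 6371 km, so a full
    longitude ring of cells sums exactly to the closed-form band area.
    """
    dlam = np.deg2rad(grid.resolution)
    lat_edges = grid.lat_min + np.arange(grid.nlat + 1) * grid.resolution
    sin_edges = np.sin(np.deg2rad(lat_edges))
    band = EARTH_RADIUS_KM**2 * dlam * (sin_edges[1:] - sin_edges[:-1])
    values = np.repeat(band[:, None], grid.nlon, axis=1)
    return RasterLayer(grid, values, variable="cell_area", units="km2")


def masked_total_area(mask: RasterLayer) -> float:
    """Total spherical area (km²) of cells that are True in ``mask``."""
    m = np.nan_to_num(mask.values.astype(float), nan=0.0) > 0
    return float(cell_areas(mask.grid).values[m].sum())


# ---------------------------------------------------------------------------
# regridding

def _block_factor(source: GridSpec, target: GridSpec) -> int:
    f = target.resolution / source.resolution
    if abs(f - round(f)) > 1e-8 or round(f) < 1:
        raise GridError(
            f"block aggregation needs target resolution {target.resolution} to be an "
            f"integer multiple of source {source.resolution}"
        )
    return int(round(f))


def _check_overlap(source: GridSpec, target: GridSpec) -> None:
    if not source.overlaps(target):
        raise GridError("source and target grids are spatially disjoint")


def _regrid_2d(values: np.ndarray, source: GridSpec, target: GridSpec,
               method: str) -> np.ndarray:
    if method in ("block_mean", "majority"):
        f = _block_factor(source, target)
        # target cells must align with blocks of f×f source cells
        i0 = (target.lat_min - source.lat_min) / source.resolution
        j0 = (target.lon_min - source.lon_min) / source.resolution
        if abs(i0 - round(i0)) > 1e-6 or abs(j0 - round(j0)) > 1e-6:
            raise GridError("target grid is not aligned with source cells")
        i0, j0 = int(round(i0)), int(round(j0))
        sub = values[i0:i0 + f * target.nlat, j0:j0 + f * target.nlon]
        if sub.shape != (f * target.nlat, f * target.nlon):
            raise GridError("target grid extends beyond the source grid")
        blocks = sub.reshape(target.nlat, f, target.nlon, f).astype(float)
        valid = np.isfinite(blocks)
        if method == "block_mean":
            # area-weighted so coarsening conserves the area-weighted mean
            w = cell_areas(source).values[i0:i0 + f * target.nlat,
                                          j0:j0 + f * target.nlon]
            w = w.reshape(target.nlat, f, target.nlon, f)
            wsum = np.where(valid, w, 0.0).sum(axis=(1, 3))
            vsum = np.where(valid, w * blocks, 0.0).sum(axis=(1, 3))
            with np.errstate(invalid="ignore"):
                return np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
        # strict majority of the valid cells in the block
        ntrue = np.where(valid, blocks > 0, False).sum(axis=(1, 3))
        nvalid = valid.sum(axis=(1, 3))
        return np.where(nvalid > 0, (ntrue * 2 > nvalid).astype(float), np.nan)
    if method in ("bilinear", "nearest"):
        _check_overlap(source, target)
        interp = RegularGridInterpolator(
            (source.lats, source.lons), values.astype(float),
            method=("linear" if method == "bilinear" else "nearest"),
            bounds_error=False, fill_value=None,
        )
        tlat, tlon = np.meshgrid(target.lats, target.lons, indexing="ij")
        return interp(np.stack([tlat.ravel(), tlon.ravel()], axis=1)).reshape(target.shape)
    raise ValueError(f"unknown regrid method {method!r}")


def regrid(layer, target: GridSpec, method: str = "bilinear"):
    """Resample a :class:`RasterLayer` or :class:`TimeSeriesStack` onto ``target``.

    ``bilinear``/``nearest`` for refining continuous fields, ``block_mean``
    for conservative coarsening, ``majority`` for Boolean masks (strict
    majority of valid contributing cells).
    """
    if isinstance(layer, RasterLayer):
        _check_overlap(layer.grid, target)
        vals = _regrid_2d(layer.values, layer.grid, target, method)
        return RasterLayer(target, vals, layer.variable, layer.units, dict(layer.attrs))
    if isinstance(layer, TimeSeriesStack):
        _check_overlap(layer.grid, target)
        out = np.empty((len(layer.times),) + target.shape)
        for i in range(len(layer.times)):
            out[i] = _regrid_2d(layer.values[i], layer.grid, target, method)
        return TimeSeriesStack(target, layer.times, layer.cadence, out,
                               layer.variable, layer.units, dict(layer.attrs))
    raise TypeError(f"cannot regrid {type(layer).__name__}")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def spherical_polygon_area_km2(geometry: BaseGeometry) -> float:
    """Area of a lon/lat polygon on the sphere, in km².

    Uses the line-integral A = R²/2 · |Σ (λ₂−λ₁)(sin φ₁ + sin φ₂)|, which is
    exact for lat/lon-aligned rectangles and accurate for the small polygons
    used here.
    """
    def ring_area(coords: Iterable[tuple[float, float]]) -> float:
        c = np.asarray(list(coords), dtype=float)
        lam = np.deg2rad(c[:, 0])
        sinphi = np.sin(np.deg2rad(c[:, 1]))
        total = np.sum((lam[1:] - lam[:-1]) * (sinphi[1:] + sinphi[:-1]))
        return abs(total) * EARTH_RADIUS_KM**2 / 2.0

    if geometry.geom_type == "Polygon":
        area = ring_area(geometry.exterior.coords)
        for hole in geometry.interiors:
            area -= ring_area(hole.coords)
        return area
    if geometry.geom_type == "MultiPolygon":
        return sum(spherical_polygon_area_km2(g) for g in geometry.geoms)
    raise TypeError(f"area undefined for {geometry.geom_type}")
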