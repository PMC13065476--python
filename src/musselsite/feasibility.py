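"""Boolean feasibility stage: heat-spike, depth, and current exclusion masks.

A cell is feasible only if it passes all three hard criteria:

* no heat-spike episode over the record (a heat spike is a run of at least
  three consecutive days with daily SST strictly above 25 °C — a
  species-specific mortality threshold for *M. edulis*, distinct from the
  climatological marine-heatwave definition);
* water depth within the 5–100 m band workable for longline culture;
* daily-average current speed never reaching 1 m s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .grid import (GridError, RasterLayer, TimeSeriesStack, VectorSet,
                   masked_total_area)


@dataclass(frozen=True)
class FeasibilityCriteria:
    heat_threshold: float = 25.0    # °C, strict
    heat_min_run: int = 3           # days
    max_episodes_allowed: int = 0   # "occurrence < 1"
    depth_min: float = 5.0          # m
    depth_max: float = 100.0        # m
    current_limit: float = 1.0      # m s⁻¹
    current_rule: str = "record_max"  # or "period_mean"

    def __post_init__(self):
        if not (0 < self.depth_min < self.depth_max):
            raise ValueError("require 0 < depth_min < depth_max")
        if self.heat_threshold <= 0 or self.current_limit <= 0 or self.heat_min_run < 1:
            raise ValueError("thresholds must be positive and min_run >= 1")
        if self.current_rule not in ("record_max", "period_mean"):
            raise ValueError("current_rule must be 'record_max' or 'period_mean'")


@dataclass
class FeasibilityResult:
    heat: RasterLayer
    depth: RasterLayer
    current: RasterLayer
    combined: RasterLayer
    area_km2: float
    episode_counts: RasterLayer | None = None
    extras: dict = field(default_factory=dict)


def _require_cadence(stack: TimeSeriesStack, cadence: str, what: str) -> None:
    if stack.cadence != cadence:
        raise GridError(f"{what} requires a {cadence} stack, got {stack.cadence!r}")


def count_heat_spike_episodes(sst: TimeSeriesStack, threshold: float = 25.0,
                              min_run: int = 3) -> RasterLayer:
    """Per-cell count of maximal runs of > threshold days with length ≥ min_run.

    Runs are maximal: a 7-day exceedance with min_run=3 is one episode.
    Missing days break runs.
    """
    _require_cadence(sst, "daily", "heat-spike counting")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = sst.values > threshold  # NaN compares False → breaks runs
    counts = np.zeros(sst.grid.shape, dtype=int)
    run = np.zeros(sst.grid.shape, dtype=int)
    for t in range(above.shape[0]):
        ended = (~above[t]) & (run >= min_run)
        counts[ended] += 1
        run = np.where(above[t], run + 1, 0)
    counts[run >= min_run] += 1  # run still open at the end of the record
    return RasterLayer(sst.grid, counts.astype(float),
                       variable="heat_spike_episodes", units="count")


def heat_mask(episode_counts: RasterLayer, max_allowed: int = 0) -> RasterLayer:
    """Feasible where the episode count does not exceed ``max_allowed`` (default 0)."""
    ok = episode_counts.values <= max_allowed
    return episode_counts.copy_with(ok.astype(float), variable="heat_ok", units="")


def depth_mask(bathymetry: RasterLayer, depth_min: float = 5.0,
               depth_max: float = 100.0) -> RasterLayer:
    """Feasible where depth_min ≤ depth ≤ depth_max (inclusive); land/missing → False.

    The bathymetry layer must declare its sign convention via
    ``attrs['convention']``: ``'depth'`` (positive down) or ``'elevation'``
    (negative below sea level).
    """
    conv = bathymetry.attrs.get("convention")
    if conv == "depth":
        depth = bathymetry.values
    elif conv == "elevation":
        depth = -bathymetry.values
    else:
        raise ValueError(
            "bathymetry must declare attrs['convention'] as 'depth' or 'elevation'"
        )
    ok = np.isfinite(depth) & (depth >= depth_min) & (depth <= depth_max)
    return bathymetry.copy_with(ok.astype(float), variable="depth_ok", units="")


def current_mask(current: TimeSeriesStack, limit: float = 1.0,
                 rule: str = "record_max") -> RasterLayer:
    """Feasible where daily-mean current speed stays below ``limit``.

    ``record_max`` (default): no daily mean over the record may reach the
    limit.  ``period_mean``: the long-term mean of daily means must stay
    below the limit.
    """
    _require_cadence(current, "daily", "current screening")
    if np.nanmin(current.values, initial=0.0) < -1e-6:
        raise ValueError("current speeds must be non-negative")
    v = current.values
    valid = np.isfinite(v)
    if rule == "record_max":
        stat = np.where(valid, v, -np.inf).max(axis=0)
        stat = np.where(np.isfinite(stat), stat, np.nan)
    elif rule == "period_mean":
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            stat = np.where(n > 0, np.where(valid, v, 0.0).sum(axis=0) / np.maximum(n, 1),
                            np.nan)
    else:
        raise ValueError("rule must be 'record_max' or 'period_mean'")
    ok = np.isfinite(stat) & (stat < limit)
    return RasterLayer(current.grid, ok.astype(float), variable="current_ok", units="")


def combine_feasibility(heat: RasterLayer, depth: RasterLayer,
                        current: RasterLayer,
                        episode_counts: RasterLayer | None = None) -> FeasibilityResult:
    """AND the three criterion masks and account the feasible area in km²."""
    if not (heat.grid == depth.grid == current.grid):
        raise GridError("criterion masks must share one GridSpec")
    combined = ((heat.values > 0) & (depth.values > 0) & (current.values > 0))
    layer = heat.copy_with(combined.astype(float), variable="feasible", units="")
    return FeasibilityResult(heat, depth, current, layer,
                             masked_total_area(layer), episode_counts)


def run_feasibility(sst: TimeSeriesStack, bathymetry: RasterLayer,
                    current: TimeSeriesStack,
                    criteria: FeasibilityCriteria = FeasibilityCriteria()
                    ) -> FeasibilityResult:
    """Full Boolean stage on one shared grid."""
    counts = count_heat_spike_episodes(sst, criteria.heat_threshold,
                                       criteria.heat_min_run)
    return combine_feasibility(
        heat_mask(counts, criteria.max_episodes_allowed),
        depth_mask(bathymetry, criteria.depth_min, criteria.depth_max),
        current_mask(current, criteria.current_limit, criteria.current_rule),
        episode_counts=counts,
    )


def count_overlapping_farms(farms: VectorSet, mask: RasterLayer
                            ) -> tuple[int, dict[str, bool]]:
    """Farms whose polygon intersects any feasible cell (partial overlap counts)."""
    grid = mask.grid
    true_idx = np.argwhere(np.nan_to_num(mask.values) > 0)
    if len(true_idx) == 0 or len(farms) == 0:
        return 0, {f.id: False for f in farms}
    res = grid.resolution
    xmin = grid.lon_min + true_idx[:, 1] * res
    ymin = grid.lat_min + true_idx[:, 0] * res
    boxes = shapely.box(xmin, ymin, xmin + res, ymin + res)
    tree = shapely.STRtree(boxes)
    flags = {}
    for f in farms:
        hits = tree.query(f.geometry, predicate="intersects")
        flags[f.id] = bool(len(hits))
    return sum(flags.values()), flags
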