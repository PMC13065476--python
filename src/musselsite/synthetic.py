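"""Seed-deterministic synthetic "mini-Europe" scenario generator.

Emulates the statistical structure of the environmental layers the
pipeline consumes — a poleward-cooling SST field with a seasonal cycle and
AR(1) weather noise, coastally enriched chlorophyll and suspended
sediment, a low-salinity sub-basin (a Baltic-like feature), a high-current
channel, storm-modulated waves, a shelf-to-deep bathymetry profile, and
rectangular wind-farm polygons with port points — without any external
download.  Land is a strip of missing cells along the eastern grid edge;
"distance from coast" is the zonal distance to that strip.

One global seed expands into fixed per-variable child seeds, so adding a
variable never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from shapely.geometry import Point, box

from .grid import Feature, GridSpec, RasterLayer, TimeSeriesStack, VectorSet, make_grid

#: fixed child-seed offsets per variable
_CHILD = {"sst": 1, "chl": 2, "sss": 3, "spm": 4, "current": 5, "waves": 6,
          "farms": 7, "ports": 8}

Box = tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max


class ScenarioConfigError(ValueError):
    """Invalid scenario configuration."""


@dataclass(frozen=True)
class SSTParams:
    south_mean: float = 14.0      # °C annual mean at the southern edge
    gradient: float = 0.75        # °C cooling per degree latitude northward
    seasonal_amplitude: float = 5.0  # °C
    noise_sd: float = 0.6         # AR(1) innovation sd, °C
    noise_rho: float = 0.7        # AR(1) day-to-day autocorrelation
    warming_south: float = 0.5    # °C projected decadal warming at the south edge
    warming_gradient: float = 0.25  # extra °C warming per degree latitude


@dataclass(frozen=True)
class HeatSpikeInjection:
    region: Box | None = None     # derived from the grid bounds when omitted
    episodes: int = 2
    duration: int = 4             # days
    exceed: float = 1.5           # °C above the 25 °C threshold


@dataclass(frozen=True)
class CHLParams:
    offshore_baseline: float = 0.8   # mg m⁻³
    coastal_enrichment: float = 3.0  # mg m⁻³ added at the coast
    decay_scale: float = 0.5         # e-folding distance, degrees
    noise_sd: float = 0.15           # lognormal sd


@dataclass(frozen=True)
class SSSParams:
    marine_baseline: float = 35.0
    basin: Box | None = None         # default: the north-western quadrant
    basin_value: float = 3.0         # Bothnian-Bay-like salinity
    noise_sd: float = 0.3


@dataclass(frozen=True)
class SPMParams:
    offshore_baseline: float = 1.0   # g m⁻³
    coastal_amplitude: float = 20.0  # g m⁻³ added at the coast
    decay_scale: float = 0.3         # degrees
    river_boxes: tuple | None = None  # default: one outflow near the SE coast
    river_amplitude: float = 25.0
    noise_sd: float = 0.2


@dataclass(frozen=True)
class CurrentParams:
    background: float = 0.2          # m s⁻¹
    channel: Box | None = None       # default: a south-central strait
    channel_peak: float = 1.3        # m s⁻¹, exceeds the 1 m s⁻¹ limit
    noise_sd: float = 0.05


@dataclass(frozen=True)
class WaveParams:
    mean: float = 1.0                # m significant wave height
    storms_per_year: float = 10.0
    storm_amplitude: float = 2.5     # m added during a storm
    storm_duration_steps: int = 16   # time steps (2 days at 3-hourly)
    noise_sd: float = 0.2
    cadence: str = "3hourly"


@dataclass(frozen=True)
class BathymetryParams:
    shelf_depth: float = 50.0        # m on the shelf
    deep_depth: float = 2000.0       # m in the offshore basin
    shelf_width: float = 2.0         # degrees of longitude from the coast
    land_fraction: float = 0.1       # fraction of lon extent that is land (east edge)


@dataclass(frozen=True)
class ScenarioConfig:
    bounds: Box = (0.0, 4.0, 50.0, 54.0)
    fine_resolution: float = 0.05
    coarse_resolution: float = 0.25
    years: int = 5
    start: str = "2019-01-01"
    sst: SSTParams = SSTParams()
    heat_spikes: tuple | None = None  # default: one injection in the south-west
    chl: CHLParams = CHLParams()
    sss: SSSParams = SSSParams()
    spm: SPMParams = SPMParams()
    current: CurrentParams = CurrentParams()
    waves: WaveParams = WaveParams()
    bathymetry: BathymetryParams = BathymetryParams()
    n_farms: int = 8
    farm_region: Box | None = None   # default: the domain inset by 5 %
    farm_size: float = 0.12          # degrees, rectangle edge scale
    status_probs: tuple = (("production", 0.5), ("accepted", 0.2), ("planned", 0.3))
    n_ports: int = 3
    seed: int = 0

    def _frac_box(self, fx0, fx1, fy0, fy1) -> Box:
        """A box expressed as fractions of the domain extent."""
        b = self.bounds
        w, h = b[1] - b[0], b[3] - b[2]
        return (b[0] + fx0 * w, b[0] + fx1 * w, b[2] + fy0 * h, b[2] + fy1 * h)

    def __post_init__(self):
        if self.years < 1:
            raise ScenarioConfigError("years must be >= 1")
        set_ = lambda k, v: object.__setattr__(self, k, v)
        if self.heat_spikes is None:
            set_("heat_spikes", (HeatSpikeInjection(),))
        set_("heat_spikes", tuple(
            hs if hs.region is not None
            else dataclasses.replace(hs, region=self._frac_box(0.05, 0.3, 0.05, 0.3))
            for hs in self.heat_spikes))
        if self.sss.basin is None:
            set_("sss", dataclasses.replace(
                self.sss, basin=self._frac_box(0.0, 0.375, 0.625, 1.0)))
        if self.spm.river_boxes is None:
            set_("spm", dataclasses.replace(
                self.spm, river_boxes=(self._frac_box(0.7, 0.85, 0.05, 0.2),)))
        if self.current.channel is None:
            set_("current", dataclasses.replace(
                self.current, channel=self._frac_box(0.375, 0.625, 0.0, 0.25)))
        if self.farm_region is None:
            set_("farm_region", self._frac_box(0.05, 0.8, 0.05, 0.95))
        for name, b in [("heat-spike", hs.region) for hs in self.heat_spikes] + \
                       [("SSS basin", self.sss.basin), ("current channel", self.current.channel),
                        ("farm region", self.farm_region)] + \
                       [("river", rb) for rb in self.spm.river_boxes]:
            if not (self.bounds[0] <= b[0] < b[1] <= self.bounds[1]
                    and self.bounds[2] <= b[2] < b[3] <= self.bounds[3]):
                raise ScenarioConfigError(f"{name} box {b} lies outside bounds {self.bounds}")

    @property
    def fine_grid(self) -> GridSpec:
        return make_grid(self.bounds, self.fine_resolution)

    @property
    def coarse_grid(self) -> GridSpec:
        return make_grid(self.bounds, self.coarse_resolution)


@dataclass
class ScenarioBundle:
    sst: TimeSeriesStack             # daily, fine grid, °C
    chl: TimeSeriesStack             # daily, fine grid, mg m⁻³
    sss: TimeSeriesStack             # monthly, coarse grid
    spm: TimeSeriesStack             # monthly, fine grid, g m⁻³
    current: TimeSeriesStack         # daily, coarse grid, m s⁻¹
    waves: TimeSeriesStack           # sub-daily, coarse grid, m
    bathymetry: RasterLayer          # fine grid, depth m (positive down), NaN = land
    ref_decadal_sst: RasterLayer     # fine grid, °C
    proj_decadal_sst: RasterLayer    # fine grid, °C
    farms: VectorSet
    ports: VectorSet
    config: ScenarioConfig


def _rng(cfg: ScenarioConfig, var: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _CHILD[var]])


def _box_mask(grid: GridSpec, b: Box) -> np.ndarray:
    lon_in = (grid.lons >= b[0]) & (grid.lons <= b[1])
    lat_in = (grid.lats >= b[2]) & (grid.lats <= b[3])
    return lat_in[:, None] & lon_in[None, :]


def _land_columns(grid: GridSpec, land_fraction: float) -> np.ndarray:
    """Boolean (lat, lon) land mask: a strip along the eastern edge."""
    n_land = int(round(grid.nlon * land_fraction))
    mask = np.zeros(grid.shape, dtype=bool)
    if n_land > 0:
        mask[:, grid.nlon - n_land:] = True
    return mask


def coast_distance_deg(grid: GridSpec, land_fraction: float) -> np.ndarray:
    """Zonal distance (degrees) from each ocean cell to the nearest land cell."""
    n_land = int(round(grid.nlon * land_fraction))
    coast_lon = grid.lon_max - n_land * grid.resolution
    d = coast_lon - grid.lons  # positive offshore (west of the coast)
    return np.clip(np.broadcast_to(d[None, :], grid.shape), 0.0, None)


def _ar1(rng, shape, sd, rho):
    """AR(1) noise along axis 0, stationary variance sd²/(1−rho²)... scaled so
    the marginal sd equals ``sd``."""
    e = rng.standard_normal(shape) * sd * np.sqrt(max(1 - rho**2, 1e-12))
    out = lfilter([1.0], [1.0, -rho], e, axis=0)
    return out


def _daily_times(cfg: ScenarioConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start)
    end = start + pd.DateOffset(years=cfg.years)
    return pd.date_range(start, end - pd.Timedelta("1d"), freq="D")


def generate_sst(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.fine_grid
    times = _daily_times(cfg)
    doy = times.dayofyear.values
    seasonal = -cfg.sst.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    lat_mean = cfg.sst.south_mean - cfg.sst.gradient * (grid.lats - cfg.bounds[2])
    base = lat_mean[None, :, None] + seasonal[:, None, None]
    noise = _ar1(_rng(cfg, "sst"), (len(times),) + grid.shape,
                 cfg.sst.noise_sd, cfg.sst.noise_rho) if cfg.sst.noise_sd > 0 else 0.0
    values = np.broadcast_to(base, (len(times),) + grid.shape).copy() + noise
    land = _land_columns(grid, cfg.bathymetry.land_fraction)
    values[:, land] = np.nan
    stack = TimeSeriesStack(grid, times, "daily", values, "SST", "degC")
    for inj in cfg.heat_spikes:
        stack = inject_heat_spikes(stack, inj.region, inj.episodes,
                                   inj.duration, inj.exceed)
    return stack


def inject_heat_spikes(sst: TimeSeriesStack, region: Box, episodes: int,
                       duration: int = 3, exceed: float = 1.5,
                       threshold: float = 25.0) -> TimeSeriesStack:
    """Force exactly ``episodes`` disjoint heat-spike runs inside ``region``.

    Each run is ``duration`` consecutive days at threshold + exceed,
    bracketed by two sub-threshold days so runs are maximal and separated.
    Cells outside the region are untouched.  ``episodes = 0`` returns the
    stack unchanged.
    """
    if duration < 1 or episodes < 0:
        raise ScenarioConfigError("require duration >= 1 and episodes >= 0")
    if episodes == 0:
        return sst
    t_total = len(sst.times)
    seg = t_total // episodes
    if seg < duration + 4:
        raise ScenarioConfigError(
            f"{t_total} days cannot hold {episodes} episodes of {duration} days "
            "with separating buffers"
        )
    mask = _box_mask(sst.grid, region)
    if not mask.any():
        raise ScenarioConfigError(f"region {region} contains no grid cells")
    values = sst.values.copy()
    sub = np.minimum(values, threshold - 1.0)  # below threshold, NaN-preserving
    for k in range(episodes):
        start = k * seg + 2  # 2-day leading buffer inside the segment
        for t in range(start - 2, start):
            values[t][mask] = sub[t][mask]
        for t in range(start, start + duration):
            spike = np.where(np.isfinite(values[t][mask]), threshold + exceed, np.nan)
            values[t][mask] = spike
        for t in range(start + duration, start + duration + 2):
            values[t][mask] = sub[t][mask]
    return TimeSeriesStack(sst.grid, sst.times, sst.cadence, values,
                           sst.variable, sst.units, dict(sst.attrs))


def generate_chl(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.fine_grid
    times = _daily_times(cfg)
    d = coast_distance_deg(grid, cfg.bathymetry.land_fraction)
    base = cfg.chl.offshore_baseline + cfg.chl.coastal_enrichment * np.exp(
        -d / cfg.chl.decay_scale)
    doy = times.dayofyear.values
    bloom = 1.0 + 0.5 * np.sin(2 * np.pi * (doy - 60) / 365.25)  # spring bloom
    noise = np.exp(_rng(cfg, "chl").normal(0.0, cfg.chl.noise_sd,
                                           (len(times),) + grid.shape)) \
        if cfg.chl.noise_sd > 0 else 1.0
    values = base[None, :, :] * bloom[:, None, None] * noise
    values[:, _land_columns(grid, cfg.bathymetry.land_fraction)] = np.nan
    return TimeSeriesStack(grid, times, "daily", values, "CHL", "mg m-3")


def _monthly_times(cfg: ScenarioConfig) -> pd.DatetimeIndex:
    return pd.date_range(pd.Timestamp(cfg.start), periods=12 * cfg.years, freq="MS")


def generate_sss(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.coarse_grid
    times = _monthly_times(cfg)
    base = np.full(grid.shape, cfg.sss.marine_baseline)
    base[_box_mask(grid, cfg.sss.basin)] = cfg.sss.basin_value
    noise = _rng(cfg, "sss").normal(0.0, cfg.sss.noise_sd,
                                    (len(times),) + grid.shape) \
        if cfg.sss.noise_sd > 0 else 0.0
    values = np.clip(base[None] + noise, 0.0, None)
    values[:, _land_columns(grid, cfg.bathymetry.land_fraction)] = np.nan
    return TimeSeriesStack(grid, times, "monthly", values, "SSS", "1e-3")


def generate_spm(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.fine_grid
    times = _monthly_times(cfg)
    d = coast_distance_deg(grid, cfg.bathymetry.land_fraction)
    base = cfg.spm.offshore_baseline + cfg.spm.coastal_amplitude * np.exp(
        -d / cfg.spm.decay_scale)
    for rb in cfg.spm.river_boxes:
        base = base + cfg.spm.river_amplitude * _box_mask(grid, rb)
    noise = np.exp(_rng(cfg, "spm").normal(0.0, cfg.spm.noise_sd,
                                           (len(times),) + grid.shape)) \
        if cfg.spm.noise_sd > 0 else 1.0
    values = base[None] * noise
    values[:, _land_columns(grid, cfg.bathymetry.land_fraction)] = np.nan
    return TimeSeriesStack(grid, times, "monthly", values, "SPM", "g m-3")


def generate_current(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.coarse_grid
    times = _daily_times(cfg)
    base = np.full(grid.shape, cfg.current.background)
    base[_box_mask(grid, cfg.current.channel)] = cfg.current.channel_peak
    noise = _rng(cfg, "current").normal(0.0, cfg.current.noise_sd,
                                        (len(times),) + grid.shape) \
        if cfg.current.noise_sd > 0 else 0.0
    values = np.clip(base[None] + noise, 0.0, None)
    values[:, _land_columns(grid, cfg.bathymetry.land_fraction)] = np.nan
    return TimeSeriesStack(grid, times, "daily", values, "current_speed", "m s-1")


def generate_waves(cfg: ScenarioConfig) -> TimeSeriesStack:
    grid = cfg.coarse_grid
    step = {"hourly": "1h", "3hourly": "3h"}[cfg.waves.cadence]
    start = pd.Timestamp(cfg.start)
    end = start + pd.DateOffset(years=cfg.years)
    times = pd.date_range(start, end, freq=step, inclusive="left")
    rng = _rng(cfg, "waves")
    n = len(times)
    storm = np.zeros(n)
    n_storms = rng.poisson(cfg.waves.storms_per_year * cfg.years)
    if n_storms > 0 and cfg.waves.storm_amplitude > 0:
        starts = rng.integers(0, max(n - cfg.waves.storm_duration_steps, 1), n_storms)
        for s in starts:
            dur = cfg.waves.storm_duration_steps
            ramp = np.sin(np.linspace(0, np.pi, dur))  # grow-and-decay envelope
            storm[s:s + dur] = np.maximum(storm[s:s + dur],
                                          cfg.waves.storm_amplitude * ramp[:n - s])
    noise = np.abs(rng.normal(0.0, cfg.waves.noise_sd, (n,) + grid.shape)) \
        if cfg.waves.noise_sd > 0 else 0.0
    values = np.clip(cfg.waves.mean + storm[:, None, None] + noise, 0.0, None)
    values[:, _land_columns(grid, cfg.bathymetry.land_fraction)] = np.nan
    return TimeSeriesStack(grid, times, cfg.waves.cadence, values,
                           "wave_height", "m")


def generate_bathymetry(cfg: ScenarioConfig) -> RasterLayer:
    """Depth raster (m, positive down): shelf near the coast, deep basin offshore,
    NaN over the land strip."""
    grid = cfg.fine_grid
    d = coast_distance_deg(grid, cfg.bathymetry.land_fraction)
    p = cfg.bathymetry
    ramp = np.clip((d - p.shelf_width) / max(p.shelf_width, 1e-9), 0.0, 1.0)
    depth = p.shelf_depth + (p.deep_depth - p.shelf_depth) * ramp
    depth[_land_columns(grid, p.land_fraction)] = np.nan
    return RasterLayer(grid, depth, variable="bathymetry", units="m",
                       attrs={"convention": "depth"})


def generate_decadal_sst(cfg: ScenarioConfig) -> tuple[RasterLayer, RasterLayer]:
    """Reference and projected decadal-mean SST (noise-free annual means)."""
    grid = cfg.fine_grid
    lat_mean = cfg.sst.south_mean - cfg.sst.gradient * (grid.lats - cfg.bounds[2])
    ref = np.broadcast_to(lat_mean[:, None], grid.shape).copy()
    warming = cfg.sst.warming_south + cfg.sst.warming_gradient * (grid.lats - cfg.bounds[2])
    proj = ref + warming[:, None]
    land = _land_columns(grid, cfg.bathymetry.land_fraction)
    ref[land] = np.nan
    proj[land] = np.nan
    mk = lambda v, n: RasterLayer(grid, v, variable=n, units="degC")
    return mk(ref, "sst_decadal_ref"), mk(proj, "sst_decadal_proj")


def generate_farms(n: int, region: Box, seed, size: float = 0.12,
                   status_probs=(("production", 0.5), ("accepted", 0.2),
                                 ("planned", 0.3))) -> VectorSet:
    """``n`` disjoint rectangular farm polygons inside ``region``."""
    if n < 0:
        raise ScenarioConfigError("n must be >= 0")
    if n == 0:
        return VectorSet([])
    rng = np.random.default_rng(seed if isinstance(seed, (list, tuple)) else [seed])
    slot = 2.0 * size
    nx = int((region[1] - region[0]) / slot)
    ny = int((region[3] - region[2]) / slot)
    if nx * ny < n:
        raise ScenarioConfigError(
            f"region {region} holds only {nx * ny} disjoint farm slots, need {n}")
    slots = rng.permutation(nx * ny)[:n]
    labels, probs = zip(*status_probs)
    statuses = rng.choice(labels, size=n, p=np.asarray(probs) / sum(probs))
    feats = []
    for k, (s, status) in enumerate(zip(slots, statuses)):
        i, j = divmod(int(s), nx)
        x0 = region[0] + j * slot + rng.uniform(0.1, 0.6) * size
        y0 = region[2] + i * slot + rng.uniform(0.1, 0.6) * size
        w = size * rng.uniform(0.7, 1.2)
        h = size * rng.uniform(0.7, 1.2)
        feats.append(Feature(f"farm-{k:03d}", f"Farm {k:03d}",
                             box(x0, y0, x0 + w, y0 + h), {"status": str(status)}))
    return VectorSet(feats)


def generate_ports(cfg: ScenarioConfig) -> VectorSet:
    """Port points just seaward of the land strip, spread in latitude."""
    grid = cfg.fine_grid
    n_land = int(round(grid.nlon * cfg.bathymetry.land_fraction))
    coast_lon = grid.lon_max - n_land * grid.resolution - grid.resolution
    rng = _rng(cfg, "ports")
    lats = np.linspace(cfg.bounds[2] + 0.3, cfg.bounds[3] - 0.3, cfg.n_ports)
    feats = [Feature(f"port-{k}", f"Port {k}",
                     Point(coast_lon, float(lat + rng.uniform(-0.1, 0.1))), {})
             for k, lat in enumerate(lats)]
    return VectorSet(feats)


def generate_scenario(cfg: ScenarioConfig = ScenarioConfig()) -> ScenarioBundle:
    """Generate the full deterministic scenario bundle for one config+seed."""
    ref, proj = generate_decadal_sst(cfg)
    return ScenarioBundle(
        sst=generate_sst(cfg),
        chl=generate_chl(cfg),
        sss=generate_sss(cfg),
        spm=generate_spm(cfg),
        current=generate_current(cfg),
        waves=generate_waves(cfg),
        bathymetry=generate_bathymetry(cfg),
        ref_decadal_sst=ref,
        proj_decadal_sst=proj,
        farms=generate_farms(cfg.n_farms, cfg.farm_region, [cfg.seed, _CHILD["farms"]],
                             cfg.farm_size, cfg.status_probs),
        ports=generate_ports(cfg),
        config=cfg,
    )
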