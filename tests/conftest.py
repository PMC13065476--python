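import numpy as np
import pandas as pd
import pytest

from musselsite.grid import GridSpec, RasterLayer, TimeSeriesStack, make_grid
from musselsite.synthetic import (CHLParams, CurrentParams, HeatSpikeInjection,
                                  ScenarioConfig, SPMParams, SSSParams,
                                  SSTParams, WaveParams, generate_scenario)


@pytest.fixture
def unit_grid() -> GridSpec:
    """4×4 grid of 0.25° cells straddling the equator."""
    return make_grid([0, 1, -0.5, 0.5], 0.25)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def daily_stack(grid: GridSpec, values: np.ndarray, variable="SST",
                units="degC", start="2020-01-01") -> TimeSeriesStack:
    times = pd.date_range(start, periods=values.shape[0], freq="D")
    return TimeSeriesStack(grid, times, "daily", values, variable, units)


def tiny_config(**overrides) -> ScenarioConfig:
    """A 1-year, 20×20-cell scenario small enough for unit tests."""
    defaults = dict(
        bounds=(0.0, 2.0, 50.0, 52.0),
        fine_resolution=0.1,
        coarse_resolution=0.5,
        years=1,
        sst=SSTParams(noise_sd=0.4),
        heat_spikes=(HeatSpikeInjection(region=(0.15, 0.75, 50.15, 50.75),
                                        episodes=2, duration=4),),
        chl=CHLParams(),
        sss=SSSParams(basin=(0.0, 0.5, 51.5, 52.0)),
        spm=SPMParams(river_boxes=((1.2, 1.6, 50.1, 50.5),)),
        current=CurrentParams(channel=(1.0, 1.5, 50.5, 51.0)),
        waves=WaveParams(),
        n_farms=5,
        farm_region=(0.1, 1.7, 50.1, 51.9),
        farm_size=0.08,
        n_ports=2,
        seed=7,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_scenario(tiny_config())


@pytest.fixture
def constant_raster(unit_grid):
    def make(value, variable="field", **attrs):
        return RasterLayer(unit_grid, np.full(unit_grid.shape, float(value)),
                           variable=variable, attrs=attrs)
    return make
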