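"""Climate-scenario suitability change.

The suitability index is recomputed with the SST factor score taken from a
decadal-mean SST field (reference decade vs projected decade, e.g.
SSP5-8.5 2040–2050), holding the other factor scores fixed, and the
percent change 100 × (Proj − Ref) / Ref is mapped.  Both the reference and
projected SI use the same decadal-mean pathway so the comparison is like
for like; the feasibility mask is not updated under projection (projected
daily SST to re-detect heat spikes does not exist at decadal cadence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridError, RasterLayer
from .suitability import (SSTResponseParams, WeightVector, sst_score,
                          weighted_overlay)


@dataclass
class ClimateScenario:
    label: str
    reference_sst: RasterLayer   # decadal-mean SST, reference decade
    projected_sst: RasterLayer   # decadal-mean SST, projected decade

    def __post_init__(self):
        if self.reference_sst.grid != self.projected_sst.grid:
            raise GridError("reference and projected SST must share one GridSpec")


def si_under_scenario(factor_means: dict, decadal_sst: RasterLayer,
                      weights: WeightVector,
                      sst_params: SSTResponseParams = SSTResponseParams()
                      ) -> RasterLayer:
    """SI with the SST factor scored from a single decadal-mean field.

    ``factor_means`` carries the non-SST mean score layers (CHL, SSS, SPM);
    any 'SST' entry present is ignored and replaced.
    """
    means = {k: v for k, v in factor_means.items() if k != "SST"}
    for layer in means.values():
        if layer.grid != decadal_sst.grid:
            raise GridError("factor grids must match the decadal SST grid")
    means["SST"] = RasterLayer(decadal_sst.grid,
                               sst_score(decadal_sst.values, sst_params),
                               variable="SST_score", units="1")
    return weighted_overlay(means, weights)


def si_percent_change(ref_si: RasterLayer, proj_si: RasterLayer) -> RasterLayer:
    """100 × (Proj − Ref)/Ref per cell; cells with Ref = 0 are missing, not ±∞."""
    if ref_si.grid != proj_si.grid:
        raise GridError("reference and projected SI must share one GridSpec")
    ref, proj = ref_si.values, proj_si.values
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (proj - ref) / ref
    pct = np.where(np.isfinite(ref) & (ref != 0) & np.isfinite(proj), pct, np.nan)
    return RasterLayer(ref_si.grid, pct, variable="SI_change", units="%")


def scenario_change(factor_means: dict, scenario: ClimateScenario,
                    weights: WeightVector,
                    sst_params: SSTResponseParams = SSTResponseParams()
                    ) -> tuple[RasterLayer, RasterLayer, RasterLayer]:
    """Reference SI, projected SI, and their percent-change map."""
    ref = si_under_scenario(factor_means, scenario.reference_sst, weights, sst_params)
    proj = si_under_scenario(factor_means, scenario.projected_sst, weights, sst_params)
    return ref, proj, si_percent_change(ref, proj)
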