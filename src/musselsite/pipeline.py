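"""Config-driven orchestration of the full site-selection pipeline.

Order of stages: scenario generation (optional) → Boolean feasibility on
the fine grid → fuzzy suitability on the coarse grid, masked by the
regridded feasibility product → auxiliary accessibility layers → climate
scenario delta → wind-farm co-location ranking.  Every threshold, weight
and seed used is recorded in the run's summary for audit, and identical
config + seed gives byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .auxiliary import AccessibilityParams, accessibility, distance_to_port, max_wave
from .climate import ClimateScenario, scenario_change
from .colocation import farm_report
from .feasibility import (FeasibilityCriteria, count_overlapping_farms,
                          run_feasibility)
from .grid import RasterLayer, cell_areas, masked_total_area, regrid
from .suitability import (DEFAULT_WEIGHTS, SI_CLASS_NAMES, SSS_PARAMS,
                          SPM_PARAMS, SSTResponseParams, ahp_weights, chl_score,
                          classify_si, consistent_matrix_from_weights,
                          mean_factor_score, spm_score, sss_score, sst_score,
                          weighted_overlay)
from .synthetic import ScenarioBundle, ScenarioConfig, generate_scenario

log = logging.getLogger("musselsite")


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    criteria: FeasibilityCriteria = field(default_factory=FeasibilityCriteria)
    access: AccessibilityParams = field(default_factory=AccessibilityParams)
    pairwise_matrix: list | None = None  # expert judgments; defaults to ratio matrix
    sst_params: SSTResponseParams = field(default_factory=SSTResponseParams)
    seed: int = 0

    def __post_init__(self):
        if self.seed != self.scenario.seed:
            self.scenario = dataclasses.replace(self.scenario, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        import musselsite.synthetic as syn

        def build(tp, payload):
            if payload is None:
                return tp()
            kw = {}
            for f in dataclasses.fields(tp):
                if f.name in payload:
                    kw[f.name] = payload[f.name]
            return tp(**kw)

        scen_payload = dict(data.get("scenario") or {})
        for key, tp in [("sst", syn.SSTParams), ("chl", syn.CHLParams),
                        ("sss", syn.SSSParams), ("spm", syn.SPMParams),
                        ("current", syn.CurrentParams), ("waves", syn.WaveParams),
                        ("bathymetry", syn.BathymetryParams)]:
            if key in scen_payload:
                scen_payload[key] = build(tp, scen_payload[key])
        if "heat_spikes" in scen_payload:
            scen_payload["heat_spikes"] = tuple(
                build(syn.HeatSpikeInjection, hs) for hs in scen_payload["heat_spikes"])
        for key in ("bounds", "farm_region"):
            if key in scen_payload:
                scen_payload[key] = tuple(scen_payload[key])
        return cls(
            scenario=build(ScenarioConfig, scen_payload),
            criteria=build(FeasibilityCriteria, data.get("criteria")),
            access=build(AccessibilityParams, data.get("access")),
            pairwise_matrix=data.get("pairwise_matrix"),
            sst_params=build(SSTResponseParams, data.get("sst_params")),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _jsonable(x):
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    return x


def compute_factor_means(bundle: ScenarioBundle, sst_params: SSTResponseParams
                         ) -> dict[str, RasterLayer]:
    """Mean factor scores on the coarse analysis grid.

    Each factor is scored at its native cadence and grid (score-then-
    average), then fine-grid means are conservatively coarsened.
    """
    coarse = bundle.config.coarse_grid
    means = {
        "SST": mean_factor_score(bundle.sst, lambda v: sst_score(v, sst_params)),
        "CHL": mean_factor_score(bundle.chl, chl_score),
        "SSS": mean_factor_score(bundle.sss, sss_score),
        "SPM": mean_factor_score(bundle.spm, spm_score),
    }
    for name, layer in means.items():
        if layer.grid != coarse:
            means[name] = regrid(layer, coarse, "block_mean")
    return means


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write rasters, the ranking CSV, and summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(config)}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("generate")
        bundle = generate_scenario(config.scenario)
        io.write_vectors(bundle.farms, outdir / "farms.geojson")
        io.write_vectors(bundle.ports, outdir / "ports.geojson")

        stage("feasibility")
        current_fine = regrid(bundle.current, bundle.config.fine_grid, "bilinear")
        current_fine.values = np.clip(current_fine.values, 0.0, None)
        feas = run_feasibility(bundle.sst, bundle.bathymetry, current_fine,
                               config.criteria)
        n_overlap, flags = count_overlapping_farms(bundle.farms, feas.combined)
        summary["feasibility"] = {
            "feasible_area_km2": feas.area_km2,
            "heat_ok_area_km2": masked_total_area(feas.heat),
            "depth_ok_area_km2": masked_total_area(feas.depth),
            "current_ok_area_km2": masked_total_area(feas.current),
            "farms_overlapping_feasible": n_overlap,
            "n_farms": len(bundle.farms),
        }
        for name, layer in [("heat_ok", feas.heat), ("depth_ok", feas.depth),
                            ("current_ok", feas.current), ("feasible", feas.combined)]:
            io.write_raster(layer, outdir / f"{name}.nc")

        stage("suitability")
        matrix = (np.asarray(config.pairwise_matrix, dtype=float)
                  if config.pairwise_matrix is not None
                  else consistent_matrix_from_weights(DEFAULT_WEIGHTS))
        ahp = ahp_weights(matrix, names=tuple(DEFAULT_WEIGHTS))
        means = compute_factor_means(bundle, config.sst_params)
        coarse = bundle.config.coarse_grid
        feas_coarse = regrid(feas.combined, coarse, "majority")
        si_unmasked = weighted_overlay(means, ahp.weights)
        si_vals = np.where(np.nan_to_num(feas_coarse.values) > 0,
                           si_unmasked.values, np.nan)
        si = si_unmasked.copy_with(si_vals)
        classes = classify_si(si)
        areas = cell_areas(coarse).values
        class_areas = {}
        for k, name in enumerate(SI_CLASS_NAMES):
            class_areas[name] = float(areas[classes.values == k].sum())
        summary["suitability"] = {
            "weights": ahp.weights.as_dict(),
            "lambda_max": ahp.lambda_max,
            "consistency_ratio": ahp.cr,
            "standardization_domains": {"SSS": SSS_PARAMS.domain,
                                        "SPM": SPM_PARAMS.domain},
            "si_area_km2": masked_total_area(
                feas_coarse.copy_with(np.isfinite(si.values).astype(float))),
            "class_areas_km2": class_areas,
            "si_mean": float(np.nanmean(si.values)) if np.isfinite(si.values).any() else None,
        }
        for name, layer in [("si", si), ("si_class", classes)] + \
                           [(f"score_{k.lower()}", v) for k, v in means.items()]:
            io.write_raster(layer, outdir / f"{name}.nc")

        stage("auxiliary")
        access = accessibility(bundle.waves, config.access.wave_limit)
        mx, mx_ok = max_wave(bundle.waves, config.access.max_wave_limit)
        dist, dist_masks = distance_to_port(coarse, bundle.ports,
                                            config.access.port_distances_nm)
        summary["auxiliary"] = {
            "mean_accessibility_pct": float(np.nanmean(access.values)),
            "max_wave_ok_area_km2": masked_total_area(mx_ok),
            "port_distance_thresholds_nm": list(config.access.port_distances_nm),
        }
        for name, layer in [("accessibility", access), ("max_wave", mx),
                            ("port_distance", dist)]:
            io.write_raster(layer, outdir / f"{name}.nc")

        stage("climate")
        scen = ClimateScenario("projection",
                               regrid(bundle.ref_decadal_sst, coarse, "block_mean"),
                               regrid(bundle.proj_decadal_sst, coarse, "block_mean"))
        ref_si, proj_si, pct = scenario_change(means, scen, ahp.weights,
                                               config.sst_params)
        pct_masked = pct.copy_with(np.where(np.isfinite(si.values), pct.values, np.nan))
        summary["climate"] = {
            "si_change_pct_min": float(np.nanmin(pct_masked.values))
            if np.isfinite(pct_masked.values).any() else None,
            "si_change_pct_max": float(np.nanmax(pct_masked.values))
            if np.isfinite(pct_masked.values).any() else None,
        }
        io.write_raster(pct_masked, outdir / "si_change_pct.nc")

        stage("colocation")
        report = farm_report(bundle.farms, si, pct_masked, access, dist)
        io.write_table(report, outdir / "farm_ranking.csv")
        top = report.head(5)
        summary["colocation"] = {
            "n_ranked": int(len(report)),
            "top_farms": [
                {k: (None if (isinstance(v, float) and not np.isfinite(v)) else _jsonable(v))
                 for k, v in row.items() if k != "unrankable"}
                for row in top.to_dict("records")
            ],
        }
    except Exception as exc:  # label the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True, allow_nan=False,
                   default=str))
    return summary
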