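"""End-to-end orchestration: simulate → covariates → ingest → fit →
validate → predict, with a plain key-value config, a resolved-config echo,
and a run log.

Every tunable carries the analysis default (35 °C / −4 °C day thresholds,
250 km station radius, up to 10 stations, 3 cfs flow cutoff, 13 km² and
2.5 % presence criteria, 9 km² home range, background multiplier 2,
collinearity cutoffs 0.7 / 10, 4 folds × 100 iterations) and is echoed in
``config_resolved.txt`` next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import ingest, io, model, synthetic, validation
from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Full pipeline configuration (key = value text file, units in names)."""

    # landscape
    nrows: int = 120
    ncols: int = 120
    cell_km: float = 1.0
    n_watersheds: int = 150
    n_stations: int = 12
    n_years: int = 10
    n_weather_years: int = 10
    n_snow_years: int = 10
    introduction_rate: float = 0.5
    dispersal_threshold_km: float = 30.0
    polygon_coverage: float = 0.6
    # covariates
    tmax_threshold_c: float = 35.0
    tmin_threshold_c: float = -4.0
    station_radius_km: float = 250.0
    max_stations: int = 10
    min_flow_cfs: float = 3.0
    home_range_km2: float = 9.0
    # ingest
    min_area_km2: float = 13.0
    min_prop: float = 0.025
    background_multiplier: int = 2
    # model
    r_cut: float = 0.7
    vif_cut: float = 10.0
    marginality: bool = True
    prediction_form: str = "exponential"
    # validation
    k_folds: int = 4
    cv_iterations: int = 100
    n_bins: int = 10
    # reproducibility
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"unknown config key {key!r} (line {lineno})")
            typ = known[key].type
            if typ in ("int", int):
                kwargs[key] = int(value)
            elif typ in ("float", float):
                kwargs[key] = float(value)
            elif typ in ("bool", bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_text(self) -> str:
        return "\n".join(f"{f.name} = {getattr(self, f.name)}"
                         for f in fields(self)) + "\n"

    def landscape_config(self) -> synthetic.LandscapeConfig:
        return synthetic.LandscapeConfig(
            nrows=self.nrows, ncols=self.ncols, cell_km=self.cell_km,
            n_watersheds=self.n_watersheds, n_stations=self.n_stations,
            n_years=self.n_years, n_weather_years=self.n_weather_years,
            n_snow_years=self.n_snow_years,
            introduction_rate=self.introduction_rate,
            dispersal_threshold_km=self.dispersal_threshold_km,
            polygon_coverage=self.polygon_coverage, seed=self.seed)


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> Path:
    """Run every stage on a synthetic landscape; returns the run directory.

    With ``resume`` true, stages whose outputs already exist are skipped and
    later stages re-read them, reproducing deleted intermediates exactly
    (everything is a pure function of config + seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pigsdm pipeline, seed={config.seed}"]
    t0 = time.time()

    def log(stage: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {stage}")

    (out / "config_resolved.txt").write_text(config.to_text())
    lcfg = config.landscape_config()

    # --- simulate ---------------------------------------------------------
    land = synthetic.generate_landscape(lcfg)
    raw = cov.compute_covariates(
        land, radius_km=config.station_radius_km,
        max_stations=config.max_stations, min_flow_cfs=config.min_flow_cfs,
        home_range_km2=config.home_range_km2)
    z_true = raw.standardize(land.watersheds.index)
    series_true = synthetic.simulate_occurrence(land, lcfg, z_true)
    polys = synthetic.emit_polygons(land, series_true,
                                    coverage=config.polygon_coverage)
    if not resume or not (out / "watersheds.geojson").exists():
        io.write_raster(out / "elevation", land.elevation, land.cell_km)
        io.write_raster(out / "flow_cfs", land.flow_cfs, land.cell_km)
        io.write_raster(out / "landcover", land.landcover, land.cell_km)
        io.write_raster(out / "snow", land.snow, land.cell_km)
        io.write_raster(out / "partition", land.partition, land.cell_km)
        io.write_stations_csv(out / "stations.csv", land.stations,
                              land.station_series)
        geoms = _watershed_geometries(land)
        io.write_watersheds_geojson(out / "watersheds.geojson",
                                    land.watersheds, geoms)
        io.write_polygons_geojson(out / "occurrence_polygons.geojson", polys)
        series_true.to_csv(out / "occurrence_true.csv", index=False)
    log("simulate")

    # --- ingest -----------------------------------------------------------
    wsh = io.read_watersheds_geojson(out / "watersheds.geojson")
    polys_in = io.read_polygons_geojson(out / "occurrence_polygons.geojson")
    series = ingest.assign_presence(polys_in, wsh,
                                    min_area_km2=config.min_area_km2,
                                    min_prop=config.min_prop)
    series = ingest.flag_introductions(
        series, wsh, dispersal_threshold_km=config.dispersal_threshold_km,
        adjacency=land.adjacency)
    series.to_csv(out / "occurrence_series.csv", index=False)
    design = ingest.build_samples(series, wsh,
                                  multiplier=config.background_multiplier,
                                  seed=config.seed)
    design.to_frame().to_csv(out / "samples.csv", index=False)
    log("ingest")

    # --- covariates (standardized on the estimation sample) ---------------
    estimation_ids = sorted(set(design.record_ids.tolist()))
    z = raw.standardize(estimation_ids)
    z.data.to_csv(out / "covariates.csv")
    (out / "standardization.json").write_text(
        json.dumps(z.meta.to_dict(), indent=1))
    log("covariates")

    # --- fit --------------------------------------------------------------
    X, y = model.build_design(z, design)
    screen = model.collinearity_screen(X, r_cut=config.r_cut,
                                       vif_cut=config.vif_cut)
    screen.pairwise_r.to_csv(out / "collinearity_r.csv")
    screen.vif.to_csv(out / "collinearity_vif.csv")
    fits = model.fit_all_subsets(X, y, marginality=config.marginality)
    model.ledger_frame(fits).to_csv(out / "subset_ledger.csv", index=False)
    avg = model.model_average(fits, meta=z.meta)
    avg.table.to_csv(out / "averaged_model.csv")
    log("fit")

    # --- validate ---------------------------------------------------------
    report = validation.cross_validate(
        X, y, k=config.k_folds, iterations=config.cv_iterations,
        n_bins=config.n_bins, marginality=config.marginality,
        seed=np.random.SeedSequence([config.seed, 1]))
    report.per_iteration.to_csv(out / "validation.csv", index=False)
    report.summary().to_csv(out / "validation_summary.csv", index=False)
    log("validate")

    # --- predict ----------------------------------------------------------
    eta = avg.linear_predictor(z, include_intercept=False)
    pred = pd.DataFrame({
        "watershed_id": z.data.index,
        "eta": eta,
        "exp_score": avg.predict(z, form="exponential"),
        "logistic_score": avg.predict(z, form="logistic"),
    })
    pred.to_csv(out / "predictions.csv", index=False)
    opt = avg.quadratic_optimum()
    (out / "quadratic_optimum.json").write_text(json.dumps(opt, indent=1))
    log("predict")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def _watershed_geometries(land) -> dict:
    import shapely
    from shapely.ops import unary_union

    cells = synthetic.watershed_cell_lists(land.partition)
    ck = land.cell_km
    return {w: unary_union(shapely.box(cc * ck, rr * ck, (cc + 1) * ck,
                                       (rr + 1) * ck))
            for w, (rr, cc) in cells.items()}
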