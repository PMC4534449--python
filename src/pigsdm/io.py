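"""Plain-format readers and writers: GeoJSON (via shapely), CSV, gridded
arrays (.npy with a JSON sidecar carrying the cell size)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape


def write_raster(path, grid: np.ndarray, cell_km: float, **attrs) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), np.asarray(grid))
    meta = {"cell_km": cell_km, "shape": list(np.asarray(grid).shape), **attrs}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_raster(path):
    path = Path(path)
    grid = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return grid, meta


def write_watersheds_geojson(path, watersheds: pd.DataFrame,
                             geometries=None) -> None:
    feats = []
    for i, row in watersheds.iterrows():
        props = {"id": int(i),
                 "centroid_x_km": float(row["centroid_x_km"]),
                 "centroid_y_km": float(row["centroid_y_km"]),
                 "centroid_elev_m": float(row["centroid_elev_m"]),
                 "area_km2": float(row["area_km2"])}
        geom = (mapping(geometries[i]) if geometries is not None
                else {"type": "Point",
                      "coordinates": [props["centroid_x_km"],
                                      props["centroid_y_km"]]})
        feats.append({"type": "Feature", "properties": props,
                      "geometry": geom})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_watersheds_geojson(path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows, geoms = [], []
    for f in gj["features"]:
        p = f["properties"]
        rows.append((p["id"], p["centroid_x_km"], p["centroid_y_km"],
                     p["centroid_elev_m"], p["area_km2"]))
        geoms.append(shape(f["geometry"]))
    df = pd.DataFrame(rows, columns=["watershed_id", "centroid_x_km",
                                     "centroid_y_km", "centroid_elev_m",
                                     "area_km2"]).set_index("watershed_id")
    df["geometry"] = geoms
    return df


def write_polygons_geojson(path, polygons: pd.DataFrame) -> None:
    feats = [{"type": "Feature",
              "properties": {"population_id": int(r.population_id),
                             "year": int(r.year)},
              "geometry": mapping(r.geometry)}
             for r in polygons.itertuples()]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_polygons_geojson(path) -> pd.DataFrame:
    gj = json.loads(Path(path).read_text())
    rows = [(f["properties"]["population_id"], f["properties"]["year"],
             shape(f["geometry"])) for f in gj["features"]]
    return pd.DataFrame(rows, columns=["population_id", "year", "geometry"])


def write_stations_csv(path, stations: pd.DataFrame,
                       series: pd.DataFrame) -> None:
    merged = series.merge(
        stations[["x_km", "y_km", "elevation_m"]],
        left_on="station_id", right_index=True)
    cols = ["station_id", "x_km", "y_km", "elevation_m", "year", "doy",
            "tmin_c", "tmax_c"]
    merged[cols].to_csv(path, index=False)


def read_stations_csv(path):
    df = pd.read_csv(path)
    stations = (df.groupby("station_id")[["x_km", "y_km", "elevation_m"]]
                .first())
    series = df[["station_id", "year", "doy", "tmin_c", "tmax_c"]].copy()
    return stations, series
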