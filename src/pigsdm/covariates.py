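"""Watershed-level habitat covariates.

Seven covariates per watershed drive the occurrence model:

- ``days_above_35`` / ``days_below_minus4`` — multi-year mean annual counts of
  hot (tmax > 35 °C) and cold (tmin < −4 °C) days at nearby weather stations,
  lapse-adjusted to the watershed centroid elevation (6.49 °C per 1000 m).
- ``snow_depth`` — multi-year mean April-1 snow depth (m), zonal mean.
- ``dist_water`` — mean Euclidean distance (km) from each cell to the nearest
  retained water cell (streams under 3 cfs removed as ephemeral).
- ``forest_pct`` / ``forage_pct`` — percent of watershed area in the forest
  (cover) and crop/mast (forage) land-cover classes.
- ``heterogeneity`` — mean number of the three key resources (water, cover,
  forage) available within a sounder home-range window (9 km²) centred on
  each cell; a continuous 0–3 index.

Covariates are z-standardized before fitting; the table retains per-column
mean/SD and the sample they came from so predictions and the hot-day optimum
can be mapped back to the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (ConfigError, ConstantColumnError, NoCoverageError,
                     NoWaterError, ShapeError)
from .synthetic import LANDCOVER_CODES, LINEAR_TERMS, Landscape

COVARIATE_COLUMNS = list(LINEAR_TERMS)

LAPSE_RATE_C_PER_KM = 6.49

# land-cover presets: the cover class from the methods text includes woody
# wetlands; an alternative without it matches the data-source table wording
FOREST_CLASSES = frozenset(
    {"deciduous_forest", "evergreen_forest", "mixed_forest", "woody_wetlands"})
FOREST_CLASSES_NO_WETLANDS = frozenset(
    {"deciduous_forest", "evergreen_forest", "mixed_forest"})
FORAGE_CLASSES = frozenset({"crop", "mast"})


@dataclass(frozen=True)
class Standardization:
    """Per-column mean/SD (sample SD, ddof=1) and the sample used."""

    mean: pd.Series
    sd: pd.Series
    sample_ids: tuple

    def to_dict(self) -> dict:
        return {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
            "sample_ids": [int(i) for i in self.sample_ids],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Standardization":
        return cls(mean=pd.Series(d["mean"], dtype=float),
                   sd=pd.Series(d["sd"], dtype=float),
                   sample_ids=tuple(d["sample_ids"]))


@dataclass
class CovariateTable:
    """One row per watershed, seven covariate columns.

    ``standardized`` marks the scale; ``meta`` holds the standardization used
    (None on the natural scale).
    """

    data: pd.DataFrame
    standardized: bool = False
    meta: Standardization | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"covariate table missing columns: {missing}")
        self.data = self.data[COVARIATE_COLUMNS].astype(float)

    def validate(self) -> None:
        """Range invariants on the natural scale."""
        if self.standardized:
            return
        d = self.data
        checks = [
            ((d["forest_pct"] >= 0) & (d["forest_pct"] <= 100)).all(),
            ((d["forage_pct"] >= 0) & (d["forage_pct"] <= 100)).all(),
            ((d["heterogeneity"] >= 0) & (d["heterogeneity"] <= 3)).all(),
            (d["dist_water"] >= 0).all(),
            ((d["days_above_35"] >= 0) & (d["days_above_35"] <= 366)).all(),
            ((d["days_below_minus4"] >= 0) & (d["days_below_minus4"] <= 366)).all(),
        ]
        if not all(checks):
            raise ConfigError("covariate range invariant violated")

    def standardize(self, sample_ids: Iterable) -> "CovariateTable":
        """z = (x − mean)/SD with mean/SD from ``sample_ids`` (sample SD)."""
        if self.standardized:
            raise ConfigError("table is already standardized")
        ids = tuple(sample_ids)
        if not ids:
            raise ConfigError("standardization sample is empty")
        sample = self.data.loc[list(dict.fromkeys(ids))]
        mean = sample.mean()
        sd = sample.std(ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            raise ConstantColumnError(
                f"constant column(s) on standardization sample: {constant}")
        z = (self.data - mean) / sd
        return CovariateTable(data=z, standardized=True,
                              meta=Standardization(mean=mean, sd=sd,
                                                   sample_ids=ids))

    def destandardize(self) -> "CovariateTable":
        if not self.standardized or self.meta is None:
            raise ConfigError("table is not standardized")
        x = self.data * self.meta.sd + self.meta.mean
        return CovariateTable(data=x, standardized=False, meta=None)


def adjust_temperature(temp_c: float, station_elev_m: float,
                       centroid_elev_m: float):
    """Lapse-adjust a station temperature to the watershed centroid elevation.

    6.49 °C per 1000 m: a centroid above the station is colder.
    """
    return temp_c - LAPSE_RATE_C_PER_KM * (centroid_elev_m - station_elev_m) / 1000.0


def _sorted_day_arrays(station_series: pd.DataFrame) -> dict:
    """station_id -> list over years of (sorted tmax, sorted tmin)."""
    out: dict = {}
    # duplicated daily records (same station, year, day) must not double-count
    cols = ["station_id", "year"] + (["doy"] if "doy" in station_series else [])
    dedup = station_series.drop_duplicates(cols)
    for (sid, _year), grp in dedup.groupby(["station_id", "year"], sort=True):
        out.setdefault(sid, []).append(
            (np.sort(grp["tmax_c"].to_numpy()), np.sort(grp["tmin_c"].to_numpy())))
    return out


def temperature_day_covariates(
    stations: pd.DataFrame,
    station_series: pd.DataFrame,
    watersheds: pd.DataFrame,
    radius_km: float = 250.0,
    max_stations: int = 10,
    tmax_threshold_c: float = 35.0,
    tmin_threshold_c: float = -4.0,
) -> pd.DataFrame:
    """Hot- and cold-day counts per watershed from nearby station records.

    For each watershed, the up-to-``max_stations`` closest stations within
    ``radius_km`` of its centroid are selected (ties broken by station id).
    Daily temperatures are lapse-adjusted to the centroid elevation *before*
    thresholding; counts are averaged over all selected station-years.
    """
    by_station = _sorted_day_arrays(station_series)
    sxy = stations[["x_km", "y_km"]].to_numpy()
    selev = stations["elevation_m"].to_numpy()
    sids = stations.index.to_numpy()

    rows = []
    for w in watersheds.itertuples():
        d = np.hypot(sxy[:, 0] - w.centroid_x_km, sxy[:, 1] - w.centroid_y_km)
        inside = d <= radius_km
        if not inside.any():
            raise NoCoverageError(
                f"no weather station within {radius_km} km of watershed {w.Index}")
        # stable sort on (distance, station id) then truncate
        order = np.lexsort((sids[inside], d[inside]))[:max_stations]
        idx = np.flatnonzero(inside)[order]
        hot, cold = [], []
        for i in idx:
            # adjusted T > thr  <=>  raw T > thr + lapse * dz
            dz_km = (w.centroid_elev_m - selev[i]) / 1000.0
            thr_hot = tmax_threshold_c + LAPSE_RATE_C_PER_KM * dz_km
            thr_cold = tmin_threshold_c + LAPSE_RATE_C_PER_KM * dz_km
            for tmax_sorted, tmin_sorted in by_station.get(sids[i], []):
                hot.append(tmax_sorted.size
                           - np.searchsorted(tmax_sorted, thr_hot, side="right"))
                cold.append(np.searchsorted(tmin_sorted, thr_cold, side="left"))
        rows.append((w.Index, float(np.mean(hot)), float(np.mean(cold))))
    return pd.DataFrame(rows, columns=["watershed_id", "days_above_35",
                                       "days_below_minus4"]
                        ).set_index("watershed_id")


def _zonal_mean(values: np.ndarray, partition: np.ndarray) -> np.ndarray:
    if values.shape != partition.shape:
        raise ShapeError(
            f"grid shape {values.shape} does not match partition {partition.shape}")
    n = int(partition.max()) + 1
    counts = np.bincount(partition.ravel(), minlength=n)
    sums = np.bincount(partition.ravel(), weights=values.ravel(), minlength=n)
    return sums / counts


def mean_snow_depth(snow: np.ndarray, partition: np.ndarray) -> pd.Series:
    """Per-watershed mean of the multi-year mean April-1 snow grid (m)."""
    snow = np.asarray(snow, dtype=float)
    if snow.ndim == 2:
        snow = snow[None]
    if snow.shape[1:] != partition.shape:
        raise ShapeError(
            f"snow grids {snow.shape[1:]} do not match partition {partition.shape}")
    return pd.Series(_zonal_mean(snow.mean(axis=0), partition),
                     name="snow_depth")


def mean_distance_to_water(flow_cfs: np.ndarray, partition: np.ndarray,
                           cell_km: float, min_flow_cfs: float = 3.0) -> pd.Series:
    """Per-watershed mean distance (km) to the nearest retained water cell.

    Water cells with mean annual flow below ``min_flow_cfs`` are removed as
    ephemeral before the Euclidean distance transform; water cells score 0.
    """
    retained = np.asarray(flow_cfs) >= min_flow_cfs
    if retained.shape != partition.shape:
        raise ShapeError("flow grid does not match partition")
    if not retained.any():
        raise NoWaterError(
            f"no water cell with flow >= {min_flow_cfs} cfs anywhere on the grid")
    dist = ndimage.distance_transform_edt(~retained, sampling=cell_km)
    return pd.Series(_zonal_mean(dist, partition), name="dist_water")


def class_mask(landcover: np.ndarray, classes: Iterable[str],
               codes: Mapping[str, int] = LANDCOVER_CODES) -> np.ndarray:
    classes = set(classes)
    unknown = classes - set(codes)
    if unknown:
        raise ConfigError(f"unknown land-cover class(es): {sorted(unknown)}")
    if not classes:
        raise ConfigError("empty land-cover class set")
    return np.isin(landcover, [codes[c] for c in classes])


def percent_cover(landcover: np.ndarray, partition: np.ndarray,
                  classes: Iterable[str],
                  codes: Mapping[str, int] = LANDCOVER_CODES) -> pd.Series:
    """Percent of each watershed's cells in the given land-cover classes."""
    mask = class_mask(landcover, classes, codes)
    if mask.shape != partition.shape:
        raise ShapeError("land-cover grid does not match partition")
    return pd.Series(100.0 * _zonal_mean(mask.astype(float), partition),
                     name="percent_cover")


def disk_footprint(radius_km: float, cell_km: float) -> np.ndarray:
    """Boolean disk of the home-range radius, in cells.

    The radius in cell units is rounded to the nearest cell; cells whose
    centre lies exactly on the boundary are included.
    """
    r = int(round(radius_km / cell_km))
    if r < 1:
        r = 1
    ax = np.arange(-r, r + 1)
    return (ax[:, None] ** 2 + ax[None, :] ** 2) <= r**2


def heterogeneity_index(water_mask: np.ndarray, cover_mask: np.ndarray,
                        forage_mask: np.ndarray, partition: np.ndarray,
                        cell_km: float,
                        home_range_km2: float = 9.0) -> pd.Series:
    """Mean per-watershed count of key resources within a home-range window.

    For each focal cell, counts how many of {water, cover, forage} have at
    least one positive cell within a circular window whose area equals the
    average sounder home range (radius sqrt(A/pi) ≈ 1.693 km for 9 km²);
    the per-watershed mean is a continuous 0–3 index.
    """
    if home_range_km2 <= 0:
        raise ConfigError("home_range_km2 must be positive")
    masks = (np.asarray(water_mask, bool), np.asarray(cover_mask, bool),
             np.asarray(forage_mask, bool))
    if len({m.shape for m in masks}) != 1 or masks[0].shape != partition.shape:
        raise ShapeError("component masks and partition must share one grid shape")
    fp = disk_footprint(np.sqrt(home_range_km2 / np.pi), cell_km)
    counts = np.zeros(partition.shape, dtype=float)
    for m in masks:
        # dilation by the disk == "any positive cell within the window"
        counts += ndimage.binary_dilation(m, structure=fp)
    return pd.Series(_zonal_mean(counts, partition), name="heterogeneity")


def compute_covariates(
    landscape: Landscape,
    forest_classes: frozenset = FOREST_CLASSES,
    forage_classes: frozenset = FORAGE_CLASSES,
    radius_km: float = 250.0,
    max_stations: int = 10,
    min_flow_cfs: float = 3.0,
    home_range_km2: float = 9.0,
) -> CovariateTable:
    """Derive the full natural-scale covariate table from a landscape."""
    temps = temperature_day_covariates(
        landscape.stations, landscape.station_series, landscape.watersheds,
        radius_km=radius_km, max_stations=max_stations)
    retained = np.asarray(landscape.flow_cfs) >= min_flow_cfs
    data = pd.DataFrame(index=landscape.watersheds.index)
    data["days_above_35"] = temps["days_above_35"]
    data["days_below_minus4"] = temps["days_below_minus4"]
    data["snow_depth"] = mean_snow_depth(landscape.snow, landscape.partition).values
    data["dist_water"] = mean_distance_to_water(
        landscape.flow_cfs, landscape.partition, landscape.cell_km,
        min_flow_cfs).values
    data["forest_pct"] = percent_cover(
        landscape.landcover, landscape.partition, forest_classes).values
    data["forage_pct"] = percent_cover(
        landscape.landcover, landscape.partition, forage_classes).values
    data["heterogeneity"] = heterogeneity_index(
        retained, class_mask(landscape.landcover, forest_classes),
        class_mask(landscape.landcover, forage_classes),
        landscape.partition, landscape.cell_km, home_range_km2).values
    table = CovariateTable(data=data)
    table.validate()
    return table
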