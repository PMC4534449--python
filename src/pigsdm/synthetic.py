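"""Synthetic landscapes, weather stations, and multi-year occurrence spread.

The generator produces the raw inputs the covariate engine and ingest stages
expect from real data — an elevation grid, a hydrography layer with flow
attributes, a land-cover classification, April-1 snow-depth grids, daily
station temperature series, and a watershed partition — with the statistical
structure the analysis assumes: spatially autocorrelated fields (Gaussian
random fields), contiguous watershed units, and a known true occurrence
surface on the standardized covariate scale.

Occurrence spread emulates an invading generalist: year-1 occupancy seeded in
the most suitable watersheds, contiguous year-over-year colonization of
adjacent watersheds with probability ``logistic(true linear predictor)``, and
rare long-distance human introductions (Poisson events beyond a dispersal
threshold, carrying a ground-truth introduction label). Occupied watersheds
stay occupied.

All randomness flows from one root seed through a fixed
``numpy.random.SeedSequence.spawn`` order (fields, flow, land cover, snow,
stations, partition, occupancy, record-level generator), so a fixed seed
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigError, ShapeError

# land-cover class codes shared across the package
LANDCOVER_CODES = {
    "other": 0,
    "deciduous_forest": 1,
    "evergreen_forest": 2,
    "mixed_forest": 3,
    "woody_wetlands": 4,
    "crop": 5,
    "mast": 6,
    "water": 7,
}

LINEAR_TERMS = (
    "days_above_35",
    "days_below_minus4",
    "snow_depth",
    "dist_water",
    "forest_pct",
    "forage_pct",
    "heterogeneity",
)
QUAD_TERM = "days_above_35_sq"
ALL_TERMS = LINEAR_TERMS + (QUAD_TERM,)


def _default_corr_lengths() -> dict:
    return {
        "elevation": 30.0,
        "water": 10.0,
        "landcover": 8.0,
        "snow": 25.0,
    }


def _default_beta() -> dict:
    # standardized-scale coefficients shaped like the published national fit:
    # strong cold/water limitation, hot-day optimum, positive heterogeneity
    return {
        "days_above_35": 0.64,
        "days_below_minus4": -2.75,
        "snow_depth": 0.0,
        "dist_water": -0.53,
        "forest_pct": 0.0,
        "forage_pct": 0.0,
        "heterogeneity": 0.20,
        QUAD_TERM: -0.12,
    }


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape and spread simulation.

    Distances are km, elevations m, temperatures °C. ``true_beta`` is on the
    standardized covariate scale and drives colonization suitability.
    """

    nrows: int = 120
    ncols: int = 120
    cell_km: float = 1.0
    n_watersheds: int = 150
    n_stations: int = 12
    n_years: int = 10
    n_weather_years: int = 10
    n_snow_years: int = 10
    corr_length_km: dict = field(default_factory=_default_corr_lengths)
    true_beta: dict = field(default_factory=_default_beta)
    true_intercept: float = -3.0
    introduction_rate: float = 0.5
    dispersal_threshold_km: float = 30.0
    seed_quantile: float = 0.01
    polygon_coverage: float = 0.6
    water_fraction: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nrows", "ncols", "n_watersheds", "n_stations",
                     "n_years", "n_weather_years", "n_snow_years"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.cell_km <= 0:
            raise ConfigError("cell_km must be positive")
        for k, v in self.corr_length_km.items():
            if v < 0:
                raise ConfigError(f"correlation length for {k!r} must be >= 0")
        if self.n_watersheds > self.nrows * self.ncols:
            raise ConfigError("more watersheds than grid cells")
        if not 0 < self.seed_quantile <= 1:
            raise ConfigError("seed_quantile must be in (0, 1]")
        unknown = set(self.true_beta) - set(ALL_TERMS)
        if unknown:
            raise ConfigError(f"unknown terms in true_beta: {sorted(unknown)}")


@dataclass
class Landscape:
    """Raw gridded and tabular inputs for one synthetic study region."""

    cell_km: float
    elevation: np.ndarray            # (nr, nc), m
    flow_cfs: np.ndarray             # (nr, nc), 0 where no water
    landcover: np.ndarray            # (nr, nc), LANDCOVER_CODES
    snow: np.ndarray                 # (n_snow_years, nr, nc), m, April-1 depth
    stations: pd.DataFrame           # station_id, row, col, x_km, y_km, elevation_m
    station_series: pd.DataFrame     # station_id, year, doy, tmin_c, tmax_c
    partition: np.ndarray            # (nr, nc), watershed id per cell
    watersheds: pd.DataFrame         # indexed by id: centroid/elev/area
    adjacency: dict                  # id -> set of adjacent ids

    @property
    def water_mask(self) -> np.ndarray:
        return self.flow_cfs > 0

    @property
    def shape(self) -> tuple:
        return self.elevation.shape


def gaussian_random_field(shape: tuple, corr_length_cells: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length.

    White noise smoothed with a Gaussian kernel of sigma equal to the
    correlation length (in cells); zero length degenerates to white noise.
    """
    z = rng.standard_normal(shape)
    if corr_length_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_length_cells, mode="reflect")
    sd = z.std()
    return (z - z.mean()) / (sd if sd > 0 else 1.0)


def _grow_partition(shape: tuple, n_watersheds: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Contiguous watershed partition: nearest-seed (discrete Voronoi) labels."""
    nr, nc = shape
    flat = rng.choice(nr * nc, size=n_watersheds, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, shape))
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cells = np.column_stack([rr.ravel(), cc.ravel()])
    _, lab = cKDTree(seeds).query(cells)
    return lab.reshape(shape).astype(np.int64)


def _partition_adjacency(partition: np.ndarray) -> dict:
    adj: dict = {int(i): set() for i in np.unique(partition)}
    for a, b in ((partition[:, :-1], partition[:, 1:]),
                 (partition[:-1, :], partition[1:, :])):
        diff = a != b
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
    return adj


def _watershed_frame(partition: np.ndarray, elevation: np.ndarray,
                     cell_km: float) -> pd.DataFrame:
    nr, nc = partition.shape
    ids = np.unique(partition)
    n = ids.size
    flat = partition.ravel()
    counts = np.bincount(flat, minlength=n).astype(float)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cy = np.bincount(flat, weights=rr.ravel(), minlength=n) / counts
    cx = np.bincount(flat, weights=cc.ravel(), minlength=n) / counts
    # centroid elevation read off the raster at the cell containing the centroid
    er = np.clip(np.rint(cy).astype(int), 0, nr - 1)
    ec = np.clip(np.rint(cx).astype(int), 0, nc - 1)
    return pd.DataFrame(
        {
            "centroid_x_km": (cx + 0.5) * cell_km,
            "centroid_y_km": (cy + 0.5) * cell_km,
            "centroid_elev_m": elevation[er, ec],
            "area_km2": counts * cell_km**2,
            "n_cells": counts.astype(int),
        },
        index=pd.Index(ids, name="watershed_id"),
    )


def _station_series(stations: pd.DataFrame, extent_y_km: float, n_years: int,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Daily min/max series per station: seasonal cycle + latitudinal and
    adiabatic gradients + day-to-day weather noise. 365-day years."""
    doy = np.arange(1, 366)
    seasonal = 10.0 * np.cos(2 * np.pi * (doy - 199) / 365.0)
    frames = []
    for s in stations.itertuples():
        # mean annual temperature: warm south (low y), cool aloft
        tmean = 22.0 - 14.0 * (s.y_km / extent_y_km) - 6.49 * s.elevation_m / 1000.0
        for year in range(1, n_years + 1):
            noise = rng.standard_normal(365) * 3.0
            mid = tmean + seasonal + noise
            frames.append(pd.DataFrame({
                "station_id": s.Index,
                "year": year,
                "doy": doy,
                "tmin_c": mid - 8.0 + rng.standard_normal(365) * 1.5,
                "tmax_c": mid + 8.0 + rng.standard_normal(365) * 1.5,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Build one seeded synthetic landscape.

    Covariate-bearing fields are Gaussian random fields with the configured
    correlation lengths; the watershed partition is a set of contiguous
    nearest-seed cell clusters; station elevations are read off the elevation
    raster at the station cell.
    """
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(8)
    shape = (config.nrows, config.ncols)
    cl = config.corr_length_km

    rng_elev = np.random.default_rng(ss[0])
    elevation = np.clip(
        800.0 + 500.0 * gaussian_random_field(
            shape, cl.get("elevation", 30.0) / config.cell_km, rng_elev),
        0.0, None)

    rng_water = np.random.default_rng(ss[1])
    gw = gaussian_random_field(shape, cl.get("water", 10.0) / config.cell_km,
                               rng_water)
    water = gw > np.quantile(gw, 1.0 - config.water_fraction)
    flow = np.zeros(shape)
    # lognormal flows; a tail below the 3 cfs ephemeral-stream cutoff
    flow[water] = np.exp(1.8 + 1.2 * rng_water.standard_normal(int(water.sum())))

    rng_lc = np.random.default_rng(ss[2])
    g_forest = gaussian_random_field(shape, cl.get("landcover", 8.0) / config.cell_km, rng_lc)
    g_ag = gaussian_random_field(shape, cl.get("landcover", 8.0) / config.cell_km, rng_lc)
    landcover = np.full(shape, LANDCOVER_CODES["other"], dtype=np.int64)
    forest = g_forest > 0.25
    ftype = rng_lc.choice(
        [LANDCOVER_CODES[c] for c in
         ("deciduous_forest", "evergreen_forest", "mixed_forest", "woody_wetlands")],
        size=shape, p=[0.4, 0.3, 0.2, 0.1])
    landcover[forest] = ftype[forest]
    crop = (~forest) & (g_ag > 0.55)
    mast = (~forest) & (~crop) & (g_ag > 0.1)
    landcover[crop] = LANDCOVER_CODES["crop"]
    landcover[mast] = LANDCOVER_CODES["mast"]
    landcover[water] = LANDCOVER_CODES["water"]

    rng_snow = np.random.default_rng(ss[3])
    yy = np.linspace(0, 1, config.nrows)[:, None] * np.ones((1, config.ncols))
    snow_base = (0.6 * gaussian_random_field(shape, cl.get("snow", 25.0) / config.cell_km, rng_snow)
                 + 1.2 * yy + (elevation - 800.0) / 1500.0)
    snow = np.clip(
        snow_base[None, :, :] * 0.4
        + 0.08 * rng_snow.standard_normal((config.n_snow_years,) + shape),
        0.0, None)

    rng_st = np.random.default_rng(ss[4])
    flat = rng_st.choice(config.nrows * config.ncols, size=config.n_stations,
                         replace=False)
    srow, scol = np.unravel_index(flat, shape)
    stations = pd.DataFrame(
        {
            "row": srow,
            "col": scol,
            "x_km": (scol + 0.5) * config.cell_km,
            "y_km": (srow + 0.5) * config.cell_km,
            "elevation_m": elevation[srow, scol],
        },
        index=pd.Index(np.arange(config.n_stations), name="station_id"),
    )
    series = _station_series(stations, config.nrows * config.cell_km,
                             config.n_weather_years, rng_st)

    rng_part = np.random.default_rng(ss[5])
    partition = _grow_partition(shape, config.n_watersheds, rng_part)

    watersheds = _watershed_frame(partition, elevation, config.cell_km)
    adjacency = _partition_adjacency(partition)
    return Landscape(
        cell_km=config.cell_km, elevation=elevation, flow_cfs=flow,
        landcover=landcover, snow=snow, stations=stations,
        station_series=series, partition=partition, watersheds=watersheds,
        adjacency=adjacency,
    )


def true_linear_predictor(covariates, config: LandscapeConfig) -> pd.Series:
    """eta = b0 + sum_j beta_j z_j on the standardized covariate scale."""
    from .covariates import CovariateTable  # local import avoids a cycle

    if isinstance(covariates, CovariateTable):
        if not covariates.standardized:
            raise ConfigError("simulate_occurrence requires standardized covariates")
        z = covariates.data
    else:
        z = covariates
    eta = pd.Series(config.true_intercept, index=z.index, dtype=float)
    for term, beta in config.true_beta.items():
        if beta == 0:
            continue
        col = z["days_above_35"] ** 2 if term == QUAD_TERM else z[term]
        eta = eta + beta * col
    return eta


def simulate_occurrence(landscape: Landscape, config: LandscapeConfig,
                        covariates) -> pd.DataFrame:
    """Simulate multi-year occupancy spread over the watershed graph.

    Returns an occurrence series with one row per occupied watershed-year
    (presence is cumulative), a ground-truth ``introduction`` flag on
    first-occupancy records created by long-distance events, and
    ``population_id`` equal to the watershed id (one population per unit).
    """
    eta = true_linear_predictor(covariates, config)
    if not eta.index.equals(landscape.watersheds.index):
        raise ShapeError("covariate table does not match the landscape watersheds")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[6])
    ids = landscape.watersheds.index.to_numpy()
    xy = landscape.watersheds[["centroid_x_km", "centroid_y_km"]].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-eta.to_numpy()))

    n_seed = max(1, int(np.ceil(config.seed_quantile * ids.size)))
    order = np.argsort(eta.to_numpy())[::-1]
    occupied = set(int(ids[i]) for i in order[:n_seed])
    first_year = {w: 1 for w in occupied}
    introduced: set = set()
    pos = {int(i): k for k, i in enumerate(ids)}

    for year in range(2, config.n_years + 1):
        frontier = sorted(
            {nb for w in occupied for nb in landscape.adjacency[w]} - occupied)
        for w in frontier:
            if rng.random() < prob[pos[w]]:
                occupied.add(w)
                first_year[w] = year
        # rare long-distance introductions beyond the dispersal threshold
        k = rng.poisson(config.introduction_rate)
        if k > 0:
            occ_xy = xy[[pos[w] for w in sorted(occupied)]]
            cand = []
            for w in sorted(set(map(int, ids)) - occupied):
                d = np.hypot(*(occ_xy - xy[pos[w]]).T)
                if d.min() > config.dispersal_threshold_km:
                    cand.append(w)
            if cand:
                for w in rng.choice(cand, size=min(k, len(cand)), replace=False):
                    w = int(w)
                    occupied.add(w)
                    first_year[w] = year
                    introduced.add(w)

    rows = []
    for year in range(1, config.n_years + 1):
        for w in sorted(w for w, fy in first_year.items() if fy <= year):
            rows.append((w, year, True,
                         w in introduced and first_year[w] == year, w))
    return pd.DataFrame(
        rows, columns=["watershed_id", "year", "present", "introduction",
                       "population_id"])


def watershed_cell_lists(partition: np.ndarray) -> dict:
    """id -> (rows, cols) arrays of member cells, in raster order."""
    order = np.argsort(partition.ravel(), kind="stable")
    flat_sorted = partition.ravel()[order]
    bounds = np.searchsorted(flat_sorted, np.arange(partition.max() + 2))
    rr, cc = np.unravel_index(order, partition.shape)
    return {int(i): (rr[bounds[i]:bounds[i + 1]], cc[bounds[i]:bounds[i + 1]])
            for i in range(partition.max() + 1)}


def emit_polygons(landscape: Landscape, series: pd.DataFrame,
                  coverage: float = 0.6) -> pd.DataFrame:
    """Emit one polygon per occupied watershed-year covering ``coverage`` of
    its area: the union of the fraction of member cells nearest the centroid.

    The emission rule is a stand-in — real survey polygons are hand-drawn —
    but it exercises both watershed-assignment criteria downstream.
    """
    import shapely
    from shapely.ops import unary_union

    if not 0 < coverage <= 1:
        raise ConfigError("coverage must be in (0, 1]")
    cells = watershed_cell_lists(landscape.partition)
    ck = landscape.cell_km
    geom_cache: dict = {}
    rows = []
    for rec in series[series["present"]].itertuples():
        w = int(rec.watershed_id)
        if w not in geom_cache:
            rr, cc = cells[w]
            cx = landscape.watersheds.loc[w, "centroid_x_km"]
            cy = landscape.watersheds.loc[w, "centroid_y_km"]
            d = np.hypot((cc + 0.5) * ck - cx, (rr + 0.5) * ck - cy)
            keep = np.argsort(d, kind="stable")[: max(1, int(round(coverage * rr.size)))]
            boxes = shapely.box(cc[keep] * ck, rr[keep] * ck,
                                (cc[keep] + 1) * ck, (rr[keep] + 1) * ck)
            geom_cache[w] = unary_union(boxes)
        rows.append((int(rec.population_id), int(rec.year), geom_cache[w]))
    return pd.DataFrame(rows, columns=["population_id", "year", "geometry"])


def simulate_discrimination_data(
    n_presence: int = 1500,
    multiplier: int = 2,
    beta: dict | None = None,
    intercept: float | None = None,
    rho: float = 0.2,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Record-level presence/background data with the discrimination model as
    exact truth.

    Draws standardized covariates from a correlated Gaussian (equicorrelation
    ``rho``), forms the design with the hot-day quadratic, and labels records
    Bernoulli(logistic(b0 + X beta)). Records with label 1 play the presence
    sample, label 0 the background sample; the class ratio is controlled by
    the intercept (default places it near 1:``multiplier``).

    Returns (X, y): X a DataFrame with the eight model terms (standardized
    linear terms plus ``days_above_35_sq``), y the 0/1 labels.
    """
    rng = np.random.default_rng(seed)
    beta = dict(_default_beta() if beta is None else beta)
    if intercept is None:
        intercept = float(np.log(1.0 / multiplier))
    p = len(LINEAR_TERMS)
    cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    L = np.linalg.cholesky(cov)

    # oversample until both classes reach target counts, then trim
    n_target0 = multiplier * n_presence
    X_parts, y_parts = [], []
    n1 = n0 = 0
    while n1 < n_presence or n0 < n_target0:
        m = 4 * (n_presence + n_target0)
        Z = rng.standard_normal((m, p)) @ L.T
        X = pd.DataFrame(Z, columns=LINEAR_TERMS)
        X[QUAD_TERM] = X["days_above_35"] ** 2
        eta = intercept + sum(
            b * X[t].to_numpy() for t, b in beta.items() if b != 0)
        y = (rng.random(m) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
        X_parts.append(X)
        y_parts.append(y)
        n1 += int(y.sum())
        n0 += int((1 - y).sum())
    X = pd.concat(X_parts, ignore_index=True)
    y = np.concatenate(y_parts)
    keep = np.concatenate([np.flatnonzero(y == 1)[:n_presence],
                           np.flatnonzero(y == 0)[:n_target0]])
    keep.sort()
    return X.iloc[keep].reset_index(drop=True), y[keep]
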