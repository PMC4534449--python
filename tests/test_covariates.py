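"""Covariate engine: lapse adjustment, zonal statistics, heterogeneity,
standardization — each checked against hand arithmetic or a brute-force
oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pigsdm as pg
from pigsdm import covariates as cov
from pigsdm.errors import (ConfigError, ConstantColumnError, NoCoverageError,
                           NoWaterError, ShapeError)

# ---------------------------------------------------------------------------
# lapse-rate adjustment


@pytest.mark.parametrize("temp,st_elev,c_elev,expected", [
    (30.0, 200.0, 1200.0, 23.51),    # 1000 m higher -> 6.49 colder
    (10.0, 500.0, 500.0, 10.0),      # no elevation difference
    (-1.0, 1500.0, 500.0, 5.49),     # 1000 m lower -> 6.49 warmer
])
def test_adjust_temperature(temp, st_elev, c_elev, expected):
    assert cov.adjust_temperature(temp, st_elev, c_elev) == pytest.approx(
        expected, abs=1e-12)


# ---------------------------------------------------------------------------
# temperature day counts

def _station_setup(records):
    """records: list of (station_id, x, y, elev, [(year, tmaxs, tmins), ...])"""
    rows = []
    meta = []
    for sid, x, y, elev, years in records:
        meta.append((sid, x, y, elev))
        for year, tmaxs, tmins in years:
            for d, (tx, tn) in enumerate(zip(tmaxs, tmins), start=1):
                rows.append((sid, year, d, tn, tx))
    stations = pd.DataFrame(meta, columns=["station_id", "x_km", "y_km",
                                           "elevation_m"]
                            ).set_index("station_id")
    series = pd.DataFrame(rows, columns=["station_id", "year", "doy",
                                         "tmin_c", "tmax_c"])
    return stations, series


def _one_watershed(x=0.0, y=0.0, elev=100.0):
    return pd.DataFrame({"centroid_x_km": [x], "centroid_y_km": [y],
                         "centroid_elev_m": [elev], "area_km2": [10.0]},
                        index=pd.Index([0], name="watershed_id"))


def test_day_counts_average_over_station_years():
    # co-located, same-elevation station: year counts {3, 5} -> mean 4.0
    years = [(1, [36.0] * 3 + [20.0] * 4, [0.0] * 7),
             (2, [36.0] * 5 + [20.0] * 2, [0.0] * 7)]
    stations, series = _station_setup([(0, 0.0, 0.0, 100.0, years)])
    out = cov.temperature_day_covariates(stations, series, _one_watershed())
    assert out.loc[0, "days_above_35"] == pytest.approx(4.0)
    assert out.loc[0, "days_below_minus4"] == 0.0


def test_lapse_applied_before_thresholding():
    # tmax 35.5 at the station, centroid 200 m higher: adjusted 34.202 -> no
    years = [(1, [35.5], [10.0])]
    stations, series = _station_setup([(0, 0.0, 0.0, 100.0, years)])
    out = cov.temperature_day_covariates(stations, series,
                                         _one_watershed(elev=300.0))
    assert out.loc[0, "days_above_35"] == 0.0
    # same day with centroid at station elevation is counted
    out2 = cov.temperature_day_covariates(stations, series,
                                          _one_watershed(elev=100.0))
    assert out2.loc[0, "days_above_35"] == 1.0


def test_radius_filter_excludes_distant_stations():
    hot_year = [(1, [36.0], [10.0])]
    cool_year = [(1, [20.0], [10.0])]
    stations, series = _station_setup([
        (0, 251.0, 0.0, 100.0, hot_year),   # outside 250 km
        (1, 10.0, 0.0, 100.0, cool_year),
    ])
    out = cov.temperature_day_covariates(stations, series, _one_watershed())
    assert out.loc[0, "days_above_35"] == 0.0


def test_no_station_in_radius_names_watershed():
    stations, series = _station_setup([(0, 900.0, 0.0, 100.0,
                                        [(1, [20.0], [0.0])])])
    with pytest.raises(NoCoverageError, match="watershed 0"):
        cov.temperature_day_covariates(stations, series, _one_watershed())


def test_day_counts_invariant_to_station_order_and_duplication():
    years_a = [(1, [36.0] * 2 + [20.0], [-5.0, 0.0, 0.0])]
    years_b = [(1, [36.0] * 4 + [20.0] * 3, [0.0] * 7)]
    stations, series = _station_setup([(0, 1.0, 0.0, 50.0, years_a),
                                       (1, 2.0, 0.0, 50.0, years_b)])
    base = cov.temperature_day_covariates(stations, series, _one_watershed(elev=50.0))

    shuffled = cov.temperature_day_covariates(
        stations.iloc[::-1], series.iloc[::-1].reset_index(drop=True),
        _one_watershed(elev=50.0))
    pd.testing.assert_frame_equal(base, shuffled)

    doubled = cov.temperature_day_covariates(
        stations, pd.concat([series, series], ignore_index=True),
        _one_watershed(elev=50.0))
    pd.testing.assert_frame_equal(base, doubled)


# ---------------------------------------------------------------------------
# snow, water distance, cover

def test_snow_zonal_means():
    part = np.zeros((4, 4), dtype=np.int64)
    part[2:, :] = 1
    zero = np.zeros((2, 4, 4))
    assert (cov.mean_snow_depth(zero, part) == 0).all()
    two_years = np.stack([np.full((4, 4), 0.10), np.full((4, 4), 0.20)])
    out = cov.mean_snow_depth(two_years, part)
    assert out.to_numpy() == pytest.approx([0.15, 0.15])


def test_snow_matches_cellwise_loop_oracle(small_landscape):
    land = small_landscape
    out = cov.mean_snow_depth(land.snow, land.partition)
    mean_grid = land.snow.mean(axis=0)
    for w in (0, 17, 63):
        expected = mean_grid[land.partition == w].mean()
        assert out[w] == pytest.approx(expected, abs=1e-12)


def test_snow_shape_mismatch():
    with pytest.raises(ShapeError):
        cov.mean_snow_depth(np.zeros((2, 3, 3)), np.zeros((4, 4), dtype=int))


def test_distance_to_water_hand_grid():
    # 3x3, one central water cell, unit cells: mean of {0, 1x4, sqrt2 x4}
    flow = np.zeros((3, 3))
    flow[1, 1] = 5.0
    part = np.zeros((3, 3), dtype=np.int64)
    out = cov.mean_distance_to_water(flow, part, cell_km=1.0)
    assert out[0] == pytest.approx((4 + 4 * np.sqrt(2)) / 9, abs=1e-9)


def test_distance_zero_on_all_water_watershed():
    flow = np.full((2, 2), 10.0)
    part = np.zeros((2, 2), dtype=np.int64)
    assert (cov.mean_distance_to_water(flow, part, 1.0) == 0).all()


def test_low_flow_streams_are_removed():
    flow = np.zeros((3, 3))
    flow[0, 0] = 2.9    # below the 3 cfs cutoff: ephemeral, dropped
    part = np.zeros((3, 3), dtype=np.int64)
    with pytest.raises(NoWaterError):
        cov.mean_distance_to_water(flow, part, 1.0)


def test_raising_flow_cutoff_never_shortens_distances(small_landscape):
    land = small_landscape
    prev = cov.mean_distance_to_water(land.flow_cfs, land.partition,
                                      land.cell_km, min_flow_cfs=1.0)
    for cut in (3.0, 6.0, 12.0):
        cur = cov.mean_distance_to_water(land.flow_cfs, land.partition,
                                         land.cell_km, min_flow_cfs=cut)
        assert (cur >= prev - 1e-12).all()
        prev = cur


def test_percent_cover_trivial_and_oracle():
    part = np.repeat(np.arange(2), 8).reshape(4, 4)
    crop = np.full((4, 4), cov.LANDCOVER_CODES["crop"])
    assert (cov.percent_cover(crop, part, {"crop"}) == 100).all()
    half = crop.copy()
    half[:, :2] = cov.LANDCOVER_CODES["other"]
    assert (cov.percent_cover(half, part, {"crop"}) == 50).all()
    with pytest.raises(ConfigError):
        cov.percent_cover(crop, part, {"martian_jungle"})


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_percent_cover_equals_counting_loop(seed):
    rng = np.random.default_rng(seed)
    landcover = rng.integers(0, 8, size=(12, 12))
    part = rng.integers(0, 3, size=(12, 12))
    # relabel so ids are 0..k-1 contiguous
    part = np.unique(part, return_inverse=True)[1].reshape(12, 12)
    classes = {"crop", "mast"}
    out = cov.percent_cover(landcover, part, classes)
    codes = {cov.LANDCOVER_CODES[c] for c in classes}
    for w in np.unique(part):
        cells = landcover[part == w]
        expected = 100.0 * sum(int(c) in codes for c in cells) / cells.size
        assert out[w] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# heterogeneity index

def _hetero_oracle(masks, partition, cell_km, home_range_km2):
    """Exhaustive per-cell window scan (independent of the dilation path)."""
    r = int(round(np.sqrt(home_range_km2 / np.pi) / cell_km))
    r = max(r, 1)
    nr, nc = partition.shape
    counts = np.zeros((nr, nc))
    for i in range(nr):
        for j in range(nc):
            c = 0
            for m in masks:
                hit = False
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        if di * di + dj * dj > r * r:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < nr and 0 <= jj < nc and m[ii, jj]:
                            hit = True
                            break
                    if hit:
                        break
                c += hit
            counts[i, j] = c
    n = partition.max() + 1
    return np.array([counts[partition == w].mean() for w in range(n)])


def test_heterogeneity_bounds():
    part = np.zeros((10, 10), dtype=np.int64)
    full = np.ones((10, 10), bool)
    empty = np.zeros((10, 10), bool)
    assert cov.heterogeneity_index(full, full, full, part, 1.0)[0] == 3.0
    assert cov.heterogeneity_index(empty, empty, empty, part, 1.0)[0] == 0.0
    with pytest.raises(ConfigError):
        cov.heterogeneity_index(full, full, full, part, 1.0,
                                home_range_km2=0)


def test_heterogeneity_single_cell_window_scan():
    water = np.zeros((7, 7), bool)
    water[3, 3] = True
    empty = np.zeros((7, 7), bool)
    part = np.zeros((7, 7), dtype=np.int64)
    # pi km^2 home range -> 1-cell radius window
    out = cov.heterogeneity_index(water, empty, empty, part, 1.0,
                                  home_range_km2=np.pi)
    expected = _hetero_oracle([water, empty, empty], part, 1.0, np.pi)
    assert out[0] == pytest.approx(expected[0], abs=1e-12)
    assert out[0] == 5 / 49  # centre + 4 rook neighbours see the water cell


@settings(derandomize=True, max_examples=5, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_heterogeneity_equals_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    shape = (20, 20)
    masks = [rng.random(shape) < 0.05 for _ in range(3)]
    part = np.unique(rng.integers(0, 4, shape), return_inverse=True)[1] \
        .reshape(shape)
    out = cov.heterogeneity_index(*masks, part, 1.0, home_range_km2=9.0)
    expected = _hetero_oracle(masks, part, 1.0, 9.0)
    np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# standardization

def test_standardize_sample_moments_and_roundtrip(small_covariates):
    ids = small_covariates.data.index
    z = small_covariates.standardize(ids)
    assert np.abs(z.data.mean()).max() < 1e-9
    assert np.abs(z.data.std(ddof=1) - 1).max() < 1e-9
    back = z.destandardize()
    assert np.abs(back.data - small_covariates.data).to_numpy().max() < 1e-12


def test_standardize_two_point_sample_uses_sample_sd():
    data = pd.DataFrame(
        {c: [0.0, 2.0] for c in pg.COVARIATE_COLUMNS},
        index=pd.Index([0, 1], name="watershed_id"))
    z = pg.CovariateTable(data=data).standardize([0, 1])
    # sample SD of {0, 2} is sqrt(2): z = -/+ 0.7071
    assert z.data.iloc[0, 0] == pytest.approx(-np.sqrt(0.5), abs=1e-9)
    assert z.data.iloc[1, 0] == pytest.approx(np.sqrt(0.5), abs=1e-9)


def test_constant_column_is_named():
    data = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in pg.COVARIATE_COLUMNS})
    data["snow_depth"] = 0.0
    with pytest.raises(ConstantColumnError, match="snow_depth"):
        pg.CovariateTable(data=data).standardize([0, 1, 2])


def test_standardization_on_subsample_centres_that_subsample(small_covariates):
    ids = list(small_covariates.data.index[:20])
    z = small_covariates.standardize(ids)
    sub = z.data.loc[ids]
    assert np.abs(sub.mean()).max() < 1e-9
    assert np.abs(sub.std(ddof=1) - 1).max() < 1e-9


def test_covariate_ranges_hold_on_synthetic_landscape(small_covariates):
    small_covariates.validate()
    d = small_covariates.data
    assert d["heterogeneity"].between(0, 3).all()
    assert d["forest_pct"].between(0, 100).all()
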