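import numpy as np
import pytest

import pigsdm as pg


@pytest.fixture(scope="session")
def small_config():
    return pg.LandscapeConfig(
        nrows=60, ncols=60, n_watersheds=80, n_stations=6, n_years=10,
        n_weather_years=3, n_snow_years=3, introduction_rate=0.6,
        dispersal_threshold_km=25.0, seed=42)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return pg.generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_covariates(small_landscape):
    return pg.compute_covariates(small_landscape)


@pytest.fixture(scope="session")
def small_standardized(small_landscape, small_covariates):
    return small_covariates.standardize(small_landscape.watersheds.index)


@pytest.fixture(scope="session")
def small_series(small_landscape, small_config, small_standardized):
    return pg.simulate_occurrence(small_landscape, small_config,
                                  small_standardized)


@pytest.fixture(scope="session")
def toy_design():
    """Record-level design with the discrimination model as exact truth."""
    X, y = pg.simulate_discrimination_data(n_presence=400, seed=99)
    return X, y
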