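import numpy as np
import pytest

from canopyscale.covariates import build_stack
from canopyscale.cwm_scaling import rasterize_landscape
from canopyscale.synthetic_landscape import (
    TRAITS,
    SimulationConfig,
    generate_landscape,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_species=80, n_plots=6)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_cwm(small_landscape):
    land = small_landscape
    rasters, report, plot_layer = rasterize_landscape(
        land.inventories, land.field_table, land.grid, list(TRAITS),
        crown_a=land.config.crown_a, crown_b=land.config.crown_b,
    )
    return rasters, report, plot_layer


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    land = small_landscape
    return build_stack(
        land.reflectance, land.grid, climate=land.climate, environment=land.environment
    )


@pytest.fixture(scope="session")
def default_landscape():
    """The default-scale landscape (50 plots) shared by the expensive tests."""
    return generate_landscape(SimulationConfig(seed=11))
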