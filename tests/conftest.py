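import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import delivloc as dl
from delivloc.synthetic_data import SimulationConfig, simulate_world


@pytest.fixture(scope="session")
def rulebook():
    return dl.load_default_rulebook()


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature world: 4 countries, 13 years, quick to simulate and fit."""
    return SimulationConfig(
        n_super_regions=1,
        n_regions_per=2,
        n_countries_per=2,
        year_start=2000,
        year_end=2012,
        n_surveys_per_country=2,
        births_per_survey=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return simulate_world(tiny_config, n_envelope_draws=25)


@pytest.fixture(scope="session")
def small_hierarchy():
    """Hand-built 6-country hierarchy over 2 regions / 2 super-regions."""
    locations = pd.DataFrame(
        {
            "location_id": ["A1", "A2", "A3", "B1", "B2", "C1"],
            "region_id": ["RA", "RA", "RA", "RB", "RB", "RC"],
            "super_region_id": ["S1", "S1", "S1", "S1", "S1", "S2"],
        }
    )
    years = np.arange(2000, 2011)
    births = pd.DataFrame(
        [
            {"location_id": loc, "year": int(y), "births": 1000 * (i + 1)}
            for i, loc in enumerate(locations["location_id"])
            for y in years
        ]
    )
    return dl.Hierarchy(locations, births)
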