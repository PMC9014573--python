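from __future__ import annotations

import pytest

from hrhplan.synthetic import (DirtConfig, SystemConfig, generate_system,
                               malawi_fixture)

SMALL_FACILITIES = {
    "urban_health_centre": 1,
    "rural_health_centre": 1,
    "community_hospital": 0,
    "district_hospital": 1,
}


@pytest.fixture(scope="session")
def fx():
    """Published 2017 national totals fixture."""
    return malawi_fixture()


@pytest.fixture(scope="session")
def small_config():
    return SystemConfig(seed=7, n_districts=4, n_central_hospitals=1,
                        n_facilities_per_type=dict(SMALL_FACILITIES))


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_system(small_config)


@pytest.fixture(scope="session")
def dirty_bundle():
    cfg = SystemConfig(seed=11, n_districts=3, n_central_hospitals=1,
                       n_facilities_per_type=dict(SMALL_FACILITIES),
                       dirt=DirtConfig(unknown_title_rate=0.1,
                                       missing_facility_rate=0.5,
                                       sparse_facility_rate=0.2))
    return generate_system(cfg)
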