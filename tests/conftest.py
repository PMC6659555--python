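import logging

import pytest

from smokesurvey.population import (
    PopulationConfig,
    PropensitySpec,
    StratumConfig,
    generate_population,
)
from smokesurvey.sampling import DesignSpec, FrameIndex, run_fieldwork

logging.getLogger("smokesurvey").setLevel(logging.ERROR)


def two_strata_config(n_adults: int = 4000, **overrides) -> PopulationConfig:
    """Small two-stratum country used across unit tests."""
    half = n_adults // 2
    base = dict(
        strata=[
            StratumConfig(stratum_id="A", region_id="R1", urbanization="urban",
                          adult_population=half, n_clusters=10),
            StratumConfig(stratum_id="B", region_id="R1",
                          urbanization="semi_urban_rural",
                          adult_population=n_adults - half, n_clusters=10),
        ],
    )
    base.update(overrides)
    return PopulationConfig(**base)


@pytest.fixture(scope="session")
def small_pop():
    return generate_population(two_strata_config(), seed=101)


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(clusters_total=8, min_clusters_per_stratum=2,
                      quota_per_cluster=10)


@pytest.fixture(scope="session")
def small_sample(small_pop, small_design):
    return run_fieldwork(small_pop, small_design, seed=202,
                         frame=FrameIndex(small_pop))


@pytest.fixture(scope="session")
def nonresponse_pop():
    """Two-stratum country where women cooperate much less than men."""
    coop = PropensitySpec(kind="constant", value=1.0,
                          by_sex={"male": 0.9, "female": 0.55})
    return generate_population(two_strata_config(cooperation=coop), seed=303)
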