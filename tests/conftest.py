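import pytest

from snapsim.cea import CostInputs
from snapsim.dietrisk import (load_junk_food_profile, load_mediated_spec,
                              load_rr_table)
from snapsim.policy import default_scenarios, load_effect_components
from snapsim.population import PopulationConfig, generate_population


@pytest.fixture(scope="session")
def medium_population():
    """100k-person synthetic population used for marginal checks."""
    return generate_population(PopulationConfig(size=100_000, seed=20180901))


@pytest.fixture(scope="session")
def small_population():
    """Small population for fast modifier/engine tests."""
    return generate_population(PopulationConfig(size=3_000, seed=11))


@pytest.fixture(scope="session")
def components():
    return load_effect_components()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture(scope="session")
def rr_table():
    return load_rr_table()


@pytest.fixture(scope="session")
def mediated():
    return load_mediated_spec()


@pytest.fixture(scope="session")
def junk_profile():
    return load_junk_food_profile()


@pytest.fixture(scope="session")
def cost_inputs():
    return CostInputs()
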