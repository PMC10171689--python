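import pytest
from hypothesis import HealthCheck, settings

from wealthproxy import (
    EconomicConfig,
    GeneratorConfig,
    default_catalogue,
    generate_cohort,
    load_weight_table,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def econ():
    return EconomicConfig()


@pytest.fixture(scope="session")
def weight_table():
    return load_weight_table()


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-household synthetic cohort with no missing instruments."""
    gen = GeneratorConfig(n=40, seed=7, n_missing_iwi=0,
                          n_missing_gapminder=0)
    return generate_cohort(gen)
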