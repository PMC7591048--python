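import numpy as np
import pytest

from econstress.simulate import GeneratorConfig, generate


def small_config(**overrides) -> GeneratorConfig:
    """A cheap three-country configuration for unit tests."""
    defaults = dict(
        n_per_country={"IT": 600, "ES": 600, "UK": 600},
        seed=123,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_data():
    """Full-size synthetic survey under the default study conditions."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_data():
    return generate(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
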