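import numpy as np
import pytest

from pearssc import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def small_pop():
    """40 fruits, 80 measured sides: enough for pipeline plumbing tests."""
    return generate_population(GeneratorConfig(n_fruits=40, seed=1))


@pytest.fixture(scope="session")
def survey_scale_pop():
    """1650 fruits / 3300 sides, matching the survey's scale."""
    return generate_population(GeneratorConfig(n_fruits=1650, seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
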