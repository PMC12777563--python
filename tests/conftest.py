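import dataclasses

import numpy as np
import pytest

from piperpk.population import PopulationParameters


@pytest.fixture(scope="session")
def pop() -> PopulationParameters:
    """The published population parameter set (package default)."""
    return PopulationParameters()


@pytest.fixture(scope="session")
def pop_novar(pop) -> PopulationParameters:
    """Same fixed effects, all variability and residual error zeroed."""
    return pop.without_variability()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_pop(pop) -> PopulationParameters:
    """Moderate-variability truth for toy-likelihood comparisons."""
    return dataclasses.replace(
        pop, gamma_cl=0.0, omega_cl=0.2, omega_v=0.2, err_a=2.0, err_b=0.1
    )
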