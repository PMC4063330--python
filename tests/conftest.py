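import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from scalartime import (
    ExperimentSpec,
    NoiseModel,
    ScalarLaw,
    derive_rate_function,
)


@pytest.fixture(scope="session")
def poisson_noise():
    return NoiseModel(beta=1.0, rho=0.5)


@pytest.fixture(scope="session")
def example_rate(poisson_noise):
    """The worked decreasing example: alpha=0.2 -> K = 62.5, n = 2, t0 = 10."""
    return derive_rate_function(
        poisson_noise, ScalarLaw.linear(0.2), tau=0.1, t0=10.0, direction="decreasing"
    )


@pytest.fixture(scope="session")
def default_spec():
    """Canonical decreasing scenario used throughout: alpha=0.05, 6 targets."""
    return ExperimentSpec(seed=1)


@pytest.fixture(scope="session")
def scenario_rate(default_spec):
    return default_spec.rate_function()
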