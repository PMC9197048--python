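import numpy as np
import pytest

from eigamma.model import (
    ConnectionGains,
    ExternalInput,
    ModelSpec,
    simulate,
)


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    return ModelSpec.default()


@pytest.fixture(scope="session")
def op_input() -> ExternalInput:
    """The oscillatory operating point used throughout: iE=3, iI=7.5."""
    return ExternalInput(iE=3.0, iI=7.5)


@pytest.fixture(scope="session")
def op_trajectory(default_spec, op_input):
    """A 5 s simulation at the operating point, shared across tests."""
    return simulate(default_spec, op_input, 5000.0)


def random_spec(rng: np.random.Generator) -> ModelSpec:
    """Randomized network weights with default sigmoids and time constants."""
    d = ModelSpec.default()
    gains = ConnectionGains(
        Wee=rng.uniform(0, 30),
        Wei=rng.uniform(1, 30),
        Wie=rng.uniform(0, 30),
        Wii=rng.uniform(0, 5),
    )
    return ModelSpec(e_params=d.e_params, i_params=d.i_params, gains=gains, taus=d.taus)


def random_input(rng: np.random.Generator) -> ExternalInput:
    return ExternalInput(iE=rng.uniform(0, 10), iI=rng.uniform(0, 20))
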