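import numpy as np
import pytest

from tibload.dataset import training_population_spec
from tibload.gaitgen import generate_muscle_set
from tibload.phantom import (PhantomSpec, generate_population,
                             landmark_weights, make_phantom)
from tibload.ssm import build_ssm


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def small_population():
    """30 corresponding phantoms from the training distribution."""
    return generate_population(30, training_population_spec(), seed=11)


@pytest.fixture(scope="session")
def trained_model(small_population):
    return build_ssm([p.cortical for p in small_population],
                     landmark_weights(40, 24))


@pytest.fixture(scope="session")
def muscle_set():
    return generate_muscle_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
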