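import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pairbond import ParameterSet, PopulationState  # noqa: E402


@pytest.fixture
def human_params():
    """Reference long-lived population: L=38, interbirth 4 yr."""
    return ParameterSet(L=38.0, beta=0.25)


@pytest.fixture
def chimp_params():
    """Reference short-lived population: L=22, interbirth 5 yr."""
    return ParameterSet(L=22.0, beta=0.2)


@pytest.fixture
def default_init():
    return PopulationState.default_initial()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_state(rng, scale=1.0):
    """A random valid population state with densities in [0, scale]."""
    return PopulationState(rng.uniform(0.0, scale, 17))


def random_params(rng):
    """A random parameter draw within the documented natural ranges."""
    return ParameterSet(
        rho=3.0,
        delta_g=0.11,
        k=rng.uniform(1.0, 2.0),
        beta=1.0 / rng.uniform(1.0, 10.0),
        q_star=rng.uniform(0.0, 1.0),
        chi=rng.choice([0.0, rng.uniform(0.0, 1.0)]),
        L=rng.uniform(20.0, 45.0),
    )
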