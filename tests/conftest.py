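import numpy as np
import pytest

import stocan as sc


@pytest.fixture(scope="session")
def birth_death():
    return sc.birth_death(2.0, 0.4)


@pytest.fixture(scope="session")
def promoter():
    return sc.two_state_promoter()


@pytest.fixture(scope="session")
def pathway_A():
    return sc.linear_pathway("A")


@pytest.fixture(scope="session")
def oscillator():
    return sc.feedback_oscillator()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def random_pathway_A(rng):
    """Network-A instance with random positive rate constants."""
    k = rng.uniform(0.3, 3.0, size=4)
    e0 = rng.uniform(2.0, 20.0)
    return sc.linear_pathway("A", k1=k[0], k2=k[1], k3=k[2], k4=k[3], e0=e0)
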