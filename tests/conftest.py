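import numpy as np
import pytest

from kinquartet import JacquardVector, jacquard_to_coefficients, validate_frequencies


def afv(*freqs):
    return validate_frequencies([(f"A{i+1}", f) for i, f in enumerate(freqs)])


@pytest.fixture
def afv631():
    return afv(0.6, 0.3, 0.1)


@pytest.fixture
def afv532():
    return afv(0.5, 0.3, 0.2)


@pytest.fixture
def afv4321():
    return afv(0.4, 0.3, 0.2, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_admissible(rng, concentration=1.0):
    """Coefficients derived from a random point on the Δ simplex."""
    d = JacquardVector(rng.dirichlet(np.full(9, concentration)))
    return d, jacquard_to_coefficients(d)
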