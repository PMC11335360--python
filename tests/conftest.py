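import numpy as np
import pytest

from svdecon import (
    assemble_matrix,
    as_rotated,
    decompose,
    gen_multiphase,
    gen_oscillatory_maps,
    gen_two_state,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_state_clean():
    """Noise-free dark-reversion-like regime: rank-2 two-state mixture."""
    return gen_two_state(noise=0.0, seed=1)


@pytest.fixture(scope="session")
def two_state_noisy():
    return gen_two_state(noise=0.01, seed=7)


@pytest.fixture(scope="session")
def multiphase_clean():
    return gen_multiphase(noise=0.0, seed=3)


@pytest.fixture(scope="session")
def multiphase_noisy():
    return gen_multiphase(noise=0.01, seed=3)


@pytest.fixture(scope="session")
def oscillatory_noisy():
    return gen_oscillatory_maps(noise=0.01, seed=5)


@pytest.fixture(scope="session")
def random_basis():
    """A generic 4-dimensional rotated-basis view of a random tall matrix."""
    rng = np.random.default_rng(99)
    a = rng.normal(size=(60, 6))
    trip = decompose(a)
    trip.rank = 4
    return as_rotated(trip)


@pytest.fixture(scope="session")
def two_state_basis(two_state_noisy):
    series, _truth = two_state_noisy
    trip = decompose(assemble_matrix(series))
    trip.rank = 2
    return trip
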