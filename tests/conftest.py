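import numpy as np
import pytest

import gardsim as g

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_beta() -> g.BetaMatrix:
    """A 20-type beta matrix at the default lognormal statistics."""
    return g.sample_beta(20, seed=101)


@pytest.fixture(scope="session")
def small_params(small_beta) -> g.GardParameters:
    return g.GardParameters(beta=small_beta, n_max=40)


@pytest.fixture(scope="session")
def default_params() -> g.GardParameters:
    """The study conditions: N_G = 100, N_MAX = 100, lognormal(-4, 4)."""
    return g.GardParameters(beta=g.sample_beta(100, seed=7), n_max=100)


@pytest.fixture(scope="session")
def short_trace(small_params) -> g.Trace:
    return g.run_trace(small_params, 40, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
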