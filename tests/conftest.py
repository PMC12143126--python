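import numpy as np
import pytest

from thetaflow import synthio


@pytest.fixture(scope="session")
def head16():
    """Small toy head model shared across tests (16 sensors, 6^3 grid)."""
    return synthio.make_toy_leadfield(16, (6, 6, 6), seed=0)


@pytest.fixture(scope="session")
def default_net():
    return synthio.default_network()


@pytest.fixture(scope="session")
def small_task():
    return synthio.TaskConfig(n_trials=24, trials_per_freq=(12, 12))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def linear_only_network(order=3):
    """Purely linear 3-node network: ATL->IFC (lag 1), IC->ATL (lag 2)."""
    A = np.zeros((order, 3, 3))
    for lag, c in enumerate([0.45, -0.25, 0.1][:order]):
        A[lag, np.arange(3), np.arange(3)] = c
    A[0, 2, 0] = 0.45
    A[1, 0, 1] = 0.35
    return synthio.GroundTruthNetwork(A)
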