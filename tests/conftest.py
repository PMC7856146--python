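import numpy as np
import pytest

from cdmnet.cotrain_ann import NetworkConfig, NetworkWeights


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_net_config():
    """Narrow, double-precision network for fast exact unit tests."""
    return NetworkConfig(hidden=(32, 16), max_epochs=60, patience=8, dtype="float64")


@pytest.fixture
def toy_weights():
    """Hand-set weights for a 3-item, C=4 network with 2-wide hidden layers.

    Small enough that the forward pass and loss can be recomputed with
    plain Python loops.
    """
    return NetworkWeights(
        W1=np.array([[0.5, -0.2], [0.1, 0.4], [-0.3, 0.2]]),
        b1=np.array([0.05, -0.1]),
        W2=np.array([[0.3, -0.5, 0.2], [0.4, 0.1, -0.2]]),
        b2=np.array([0.0, 0.2, -0.1]),
        W3=np.array([[0.2, -0.1, 0.3, 0.0], [0.1, 0.2, -0.4, 0.3], [-0.2, 0.1, 0.0, 0.2]]),
        b3=np.array([0.01, -0.02, 0.03, 0.0]),
        V1=np.array(
            [[2.0, 0.1, -0.3, 0.2], [0.0, 1.8, 0.2, -0.1], [0.3, -0.2, 2.2, 0.1], [0.1, 0.0, -0.1, 1.9]]
        ),
        V2=np.array(
            [[1.7, -0.1, 0.2, 0.0], [0.2, 2.1, -0.2, 0.1], [-0.1, 0.3, 1.8, 0.0], [0.0, 0.1, 0.2, 2.0]]
        ),
        Wr=np.array(
            [[0.5, -0.3, 0.2], [-0.2, 0.4, 0.1], [0.3, 0.0, -0.4], [0.1, 0.2, 0.3]]
        ),
        br=np.array([0.02, -0.05, 0.1]),
    )


@pytest.fixture
def toy_batch():
    """Two response patterns plus one-hot labels matching the toy network."""
    X = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
    Y1 = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
    Y2 = np.array([[0.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
    return X, Y1, Y2
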