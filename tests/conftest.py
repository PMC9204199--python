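import numpy as np
import pytest

from vnsmpc.datagen import NormStats, generate_dataset
from vnsmpc.params import healthy_parameters


class LinearSurrogate:
    """Stateless linear stand-in for the recurrent surrogate.

    In normalized space: y_{k+1} = A y_k + B u_k. Implements the interface
    the controller needs (norm, init_state, step), with analytically known
    behaviour for oracle comparisons.
    """

    def __init__(self, A, B, norm):
        self.A = np.asarray(A, dtype=float)
        self.B = np.asarray(B, dtype=float)
        self.norm = norm

    def init_state(self, batch=1):
        return [(np.zeros((batch, 0)),)]

    def step(self, x, state, collect=None):
        y = x[:, :2] @ self.A.T + x[:, 2:] @ self.B.T
        return y, state, None


@pytest.fixture(scope="session")
def unit_norm():
    """Identity scaling on outputs (span 1); commands scaled by their bounds."""
    mu = np.zeros(8)
    lo = np.array([-0.5, -0.5, 0, 0, 0, 0, 0, 0])
    hi = np.array([0.5, 0.5, 0.5, 50, 0.5, 50, 0.5, 50])
    return NormStats(mu=mu, x_min=lo, x_max=hi)


@pytest.fixture(scope="session")
def linear_model(unit_norm):
    A = np.diag([0.9, 0.8])
    B = np.array([[0.05, 0.0, 0.0, 0.0, -0.03, 0.0],
                  [0.0, 0.04, 0.0, 0.03, 0.0, -0.02]])
    return LinearSurrogate(A, B, unit_norm)


@pytest.fixture(scope="session")
def healthy():
    """The shipped healthy preset (frozen at its calibrated operating point)."""
    return healthy_parameters()


@pytest.fixture(scope="session")
def small_dataset(healthy):
    """A 60-trial open-loop dataset for fast surrogate/datagen tests."""
    return generate_dataset(healthy, 60, seed=11)
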