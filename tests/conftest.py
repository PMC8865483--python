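import numpy as np
import pytest

from mousemsk.fixtures import pendulum_fixture, two_dof_chain_fixture


@pytest.fixture(scope="session")
def pendulum():
    """Two-segment hinge model, a = b = 10 mm, with closed-form lmt/r."""
    return pendulum_fixture(10.0, 10.0)


@pytest.fixture(scope="session")
def chain():
    """Three-segment chain with two hinges and one bi-articular muscle."""
    return two_dof_chain_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
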