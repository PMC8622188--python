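import numpy as np
import pytest

import dnapendulum as dp


@pytest.fixture(scope="session")
def seq10():
    """Seeded 10-bp random sequence shared by the integrator checks."""
    return dp.random_sequence(dp.SequenceSpec(n=10, seed=5))


@pytest.fixture(scope="session")
def system10(seq10):
    return dp.build_system(seq10, lam=1.0)


@pytest.fixture()
def small_trajectory():
    """Hand-built trajectory with known angles for observable tests."""
    times = np.linspace(0.0, 1e-9, 11)
    phi = np.zeros((11, 2, 4))
    omega = np.zeros_like(phi)
    return dp.Trajectory(times=times, phi=phi, omega=omega)
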