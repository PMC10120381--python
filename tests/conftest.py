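import numpy as np
import pytest

from darkadapt import (DAParams, StaircaseProtocol, make_observer,
                       simulate_staircase)

#: Test duration used by the default protocol, seconds.
DURATION = 2100.0


def random_valid_params(rng: np.random.Generator,
                        duration: float = DURATION) -> DAParams:
    """A random parameter draw satisfying all model invariants."""
    return DAParams(
        Bc=rng.uniform(-3.0, 0.5),
        Ic=rng.uniform(0.1, 4.0),
        Rc=-10 ** rng.uniform(-3.0, -1.5),
        Ir=rng.uniform(0.1, 60.0),
        Rr=-10 ** rng.uniform(-3.5, -2.0),
        tb=rng.uniform(60.0, duration - 60.0),
    )


@pytest.fixture(scope="session")
def protocol():
    return StaircaseProtocol()


@pytest.fixture(scope="session")
def healthy_observer():
    """Observer with the outcome profile of a typical healthy control."""
    return make_observer(-1.56, -4.23, 11.4, slope=10.0, lapse_rate=0.02,
                         rng_seed=7)


@pytest.fixture(scope="session")
def healthy_staircase(healthy_observer, protocol):
    return simulate_staircase(healthy_observer, protocol)
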