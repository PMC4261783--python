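import numpy as np
import pytest

from odefit.data_gen import load_benchmark
from odefit.ode_models import ODEModel, TimeSeries, erk_model, g1s_model


@pytest.fixture(scope="session")
def g1s():
    return g1s_model()


@pytest.fixture(scope="session")
def erk():
    return erk_model()


@pytest.fixture(scope="session")
def g1s_dataset():
    return load_benchmark("g1s")


@pytest.fixture(scope="session")
def erk_dataset():
    return load_benchmark("erk")


@pytest.fixture(scope="session")
def toy_decay_model():
    """1-parameter linear decay dX/dt = -theta * X from X(0) = 1."""
    return ODEModel(
        name="toy_decay",
        state_names=("x",),
        param_names=("theta",),
        rhs=lambda y, p, t: (-p[0] * y[0],),
        default_initial_state=(1.0,),
        wmax=2.0,
        exact_params=(0.5,),
    )


@pytest.fixture(scope="session")
def toy_decay_obs(toy_decay_model):
    times = np.linspace(0.0, 5.0, 6)
    values = np.exp(-0.5 * times)[None, :]
    return TimeSeries(times, values, ("x",))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
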