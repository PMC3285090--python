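import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stemca import SimulationParameters, run_simulation

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session", autouse=True)
def warm_engine():
    """Compile the step kernels once per session on a tiny run."""
    run_simulation(
        SimulationParameters(lattice_size=30, max_cells=60, max_time_h=480.0),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_params():
    """Parameters for fast unit-level runs on a small lattice."""

    def make(**overrides):
        defaults = dict(
            rho_max=2,
            p_s=0.1,
            mu=5,
            lattice_size=60,
            max_cells=500,
            max_time_h=4000.0,
        )
        defaults.update(overrides)
        return SimulationParameters(**defaults)

    return make
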