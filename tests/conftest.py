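import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from locusdyn.config import PopulationConfig
from locusdyn.synthetic.population import simulate_population
from locusdyn.synthetic.render import render_stack

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    """Six-cell population covering all behaviour classes, 12 frames."""
    cfg = PopulationConfig(
        n_cells=6,
        n_frames=12,
        seed=42,
        class_fractions={
            "integrated": 2 / 6,
            "mobile_fast": 2 / 6,
            "mobile_local": 1 / 6,
            "trapped": 1 / 6,
        },
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def rendered_field(small_population):
    """Default-noise rendering of the six-cell population."""
    return render_stack(small_population, 0)


@pytest.fixture(scope="session")
def noiseless_population():
    """Three-cell integrated population rendered without camera noise."""
    cfg = PopulationConfig(
        n_cells=3,
        n_frames=4,
        seed=7,
        photon_budget=float("inf"),
        read_noise=0.0,
        background=0.0,
        class_fractions={"integrated": 1.0},
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_population):
    return render_stack(noiseless_population, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
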