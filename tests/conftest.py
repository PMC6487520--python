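import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pea():
    from seedbo.parameter_space import pea_space
    return pea_space()


@pytest.fixture
def space1d():
    from seedbo.parameter_space import single_temperature_space
    return single_temperature_space()


@pytest.fixture
def toy_fit_1d():
    """Deterministic 1-D GP fit with a single interior bump, fixed hyperparameters."""
    from seedbo.gp_model import GPFit, KernelHyperparams
    X = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
    y = np.array([0.0, 0.4, 1.2, 0.5, 0.0])
    h = KernelHyperparams(1.0, 0.2, 0.02)
    return GPFit(h, float(y.mean()), X, y)
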