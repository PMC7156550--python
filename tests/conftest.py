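import numpy as np
import pytest

from lymphokin import (
    EventTimeDistribution,
    FitBudget,
    PopulationSpec,
)
from lymphokin.synthetic import DEFAULT_HEAVY_WATER, default_schedule

#: optimizer effort used throughout the suite: enough for reliable recovery on
#: these problem sizes while keeping the full run fast
LEAN_BUDGET = FitBudget(n_starts=32, n_polish=2, polish_maxfev=300)


@pytest.fixture(scope="session")
def heavy_water():
    return DEFAULT_HEAVY_WATER


@pytest.fixture(scope="session")
def schedule11():
    return default_schedule(11)


@pytest.fixture(scope="session")
def exp_spec():
    """Homogeneous age-independent population, mean event time 200 days."""
    return PopulationSpec.homogeneous(EventTimeDistribution.exponential(200.0))


@pytest.fixture(scope="session")
def cyton_spec():
    """Homogeneous gamma cyton, shape 8, mean event time 150 days."""
    return PopulationSpec.homogeneous(EventTimeDistribution.gamma(8.0, 150.0 / 8.0))


@pytest.fixture(scope="session")
def risk_spec():
    """Homogeneous gamma risk, shape 0.3, mean event time 200 days."""
    return PopulationSpec.homogeneous(EventTimeDistribution.gamma(0.3, 200.0 / 0.3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
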