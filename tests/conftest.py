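import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biasblend as bb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # short test chains may trip the (honest) convergence flags; the flag
    # itself is asserted where it matters
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", bb.ConvergenceWarning)
        yield


@pytest.fixture
def small_table():
    """Deterministic 3-area x 3-source table with known structure."""
    y = np.array([
        [21.0, 19.5, 24.0],
        [25.0, 23.0, 27.5],
        [23.0, 21.0, 25.5],
    ])
    se = np.array([
        [1.0, 0.8, 1.2],
        [1.1, 0.9, 1.0],
        [0.9, 1.0, 1.1],
    ])
    return bb.EstimateTable(["north", "mid", "south"], ["official", "commercial", "ward"], y, se)


@pytest.fixture(scope="session")
def default_table():
    """One study-sized synthetic dataset (48 areas x 7 sources)."""
    table, truth = bb.simulate_dataset(bb.SimConfig(seed=3))
    return table, truth


def short_mcmc(seed=0, n_iter=900, n_burnin=300, n_chains=2):
    return bb.McmcConfig(n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin,
                         seed=seed)
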