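import numpy as np
import pandas as pd
import pytest

from fedabund.io import StudyConfig
from fedabund.simulate import Scenario, SimulationParams, simulate_study

TINY_SCENARIO = Scenario("tiny", (12, 10, 8), (6, 5, 4), (0.3, 0.3, 0.3))
TINY_PARAMS = SimulationParams(
    n_proteins=150, de_block=15, conf_block=10, mv_rate=0.15, mnar_rate=0.5
)


@pytest.fixture(scope="session")
def tiny_study():
    """Small three-cohort study with counts: (bundles, truth, samples)."""
    return simulate_study(TINY_SCENARIO, TINY_PARAMS, seed=11, with_counts=True)


@pytest.fixture()
def tiny_config():
    return StudyConfig(
        expected_clients=3, normalization="none", use_counts=True, seed=11
    )


@pytest.fixture()
def two_group_data():
    """Complete 80-protein two-group matrix with heterogeneous variances."""
    rng = np.random.default_rng(7)
    n, m_a, m_b = 80, 6, 5
    sig = np.sqrt(3.0 / rng.gamma(2.5, 1.0, size=n))
    y = rng.normal(5.0, 1.0, size=(n, m_a + m_b)) * sig[:, None]
    y[:10, :m_a] += 2.0
    X = np.zeros((m_a + m_b, 2))
    X[:m_a, 0] = 1.0
    X[m_a:, 1] = 1.0
    return y, X, m_a, m_b
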