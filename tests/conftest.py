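import numpy as np
import pytest

from semisurv import SimulationConfig, SurvivalDataset, simulate_dataset


@pytest.fixture
def toy_km_dataset():
    """Times (1, 2+, 3, 4): events at 1, 3, 4, censored at 2."""
    return SurvivalDataset(X=np.zeros((4, 1)), time=[1.0, 2.0, 3.0, 4.0],
                           status=[1, 0, 1, 1])


@pytest.fixture(scope="session")
def small_sim():
    """Moderate-signal dataset small enough for fast penalized fits."""
    return simulate_dataset(SimulationConfig(n=120, p=60, n_informative=5,
                                             rho=0.0, censor_rate=0.4, seed=42))


@pytest.fixture(scope="session")
def lowdim_sim():
    """p << n dataset for unpenalized-oracle comparisons."""
    beta = np.array([0.8, -0.5, 0.0])
    return simulate_dataset(SimulationConfig(n=60, p=3, n_informative=2,
                                             beta_true=beta, rho=0.0,
                                             censor_rate=0.3, seed=3))
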