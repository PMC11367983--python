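import numpy as np
import pytest

from ndfa import (
    BalanceDataset,
    BayesConfig,
    BetaParams,
    assemble_priors,
    scenario_preset,
    simulate_balance_dataset,
)

# reference informative theta priors used across tests
FIELD_PEA_THETA = BetaParams(9.04, 5.00)
WHITE_LUPIN_THETA = BetaParams(62.52, 14.06)


@pytest.fixture(scope="session")
def field_pea_priors():
    """Informative prior set for the wide-range (Scenario A) regime."""
    return assemble_priors(FIELD_PEA_THETA, species="field pea", kind="pnb")


@pytest.fixture(scope="session")
def white_lupin_priors():
    """Informative prior set for the boundary (Scenario B) regime."""
    return assemble_priors(WHITE_LUPIN_THETA, species="white lupin", kind="pnb")


@pytest.fixture(scope="session")
def scenario_a_data():
    return simulate_balance_dataset(scenario_preset("A", seed=7))


@pytest.fixture
def quick_config():
    """A short but convergent MCMC configuration for unit tests."""
    return BayesConfig(chains=4, iterations_total=6000, warmup_total=3000, seed=11)


@pytest.fixture
def empty_dataset():
    return BalanceDataset(x=np.array([]), y=np.array([]), balance_kind="pnb")
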