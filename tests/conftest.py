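import warnings

import numpy as np
import pytest

import cbgam

TEST_SEED = 0  # suite-wide seed convention


@pytest.fixture(scope="session")
def cohort70():
    return cbgam.generate_cohort(n_patients=70, seed=TEST_SEED)


@pytest.fixture(scope="session")
def cohort2000():
    return cbgam.generate_cohort(n_patients=2000, seed=TEST_SEED)


@pytest.fixture(scope="session")
def cohort10000():
    return cbgam.generate_cohort(n_patients=10000, seed=TEST_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)


@pytest.fixture(scope="session")
def developed2000(cohort2000):
    """One full five-step protocol run at reduced ensemble size, shared by
    the recovery-style tests (grid search + B=500 ensemble, ~1 min)."""
    from cbgam.protocol import ProtocolConfig, develop_model

    cfg = ProtocolConfig(B_estimate=500, seed=TEST_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return develop_model(cohort2000, cfg)
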