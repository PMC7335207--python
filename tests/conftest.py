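import numpy as np
import pytest

import chrev
from chrev import cohort as coh


@pytest.fixture(scope="session")
def exp1_design():
    return chrev.experiment_design(1, seed=11)


@pytest.fixture(scope="session")
def exp5_design():
    return chrev.experiment_design(5, seed=11)


@pytest.fixture(scope="session")
def model2_params():
    return coh.AgentParams(alpha_learning=0.3, tau=0.15, alpha_ch=0.3, model_id=2)


@pytest.fixture(scope="session")
def model2_dataset(exp1_design, model2_params):
    """One synthetic participant simulated from model 2 on the experiment-1
    design; reused wherever a realistic choice log is needed."""
    return coh.simulate_agent(model2_params, exp1_design, seed=7)


@pytest.fixture(scope="session")
def small_cohort(exp1_design):
    """A small model-2 cohort for group-level statistics tests."""
    return coh.generate_cohort(16, exp1_design, seed=21, model_id=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
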