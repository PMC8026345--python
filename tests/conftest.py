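import warnings

import pytest

from navlearn.cohort import (
    DEFAULT_ARCHETYPES,
    behavioral_schedule,
    build_schedule,
    simulate_subject,
)
from navlearn.io import SamplerConfig
from navlearn.statespace import fit_block_model, fit_trial_model

warnings.filterwarnings("ignore", category=FutureWarning)

#: desk-scale sampler shared by the fitting tests
TEST_CFG = SamplerConfig(chains=4, iterations=1000, warmup=500, seed=0)


@pytest.fixture(scope="session")
def behavioral_spec():
    return behavioral_schedule()


@pytest.fixture(scope="session")
def good_subject(behavioral_spec):
    """One good-learner subject with its planted latent trajectory."""
    plan = build_schedule(behavioral_spec, seed=1)
    trials, truth = simulate_subject(
        DEFAULT_ARCHETYPES["good"], plan, "young", seed=3,
        spec=behavioral_spec, subject_id="G01",
    )
    return trials, truth


@pytest.fixture(scope="session")
def block_posterior(good_subject):
    trials, _ = good_subject
    return fit_block_model(trials, TEST_CFG)


@pytest.fixture(scope="session")
def trial_posterior(good_subject):
    trials, _ = good_subject
    return fit_trial_model(trials, TEST_CFG)
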