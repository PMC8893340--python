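import warnings

import numpy as np
import pytest

import conformity as cf

# statsmodels emits boundary-convergence warnings when a variance component
# is estimated near zero; they are expected in small simulated fits
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, per-condition generative mode, fixed seed."""
    return cf.generate_cohort(12, seed=42)


@pytest.fixture(scope="session")
def annotated_small(small_cohort):
    return cf.annotate(small_cohort.trials)


@pytest.fixture(scope="session")
def one_session():
    rng = np.random.default_rng(7)
    agent = cf.ParticipantAgent(cf.AgentParams(), "p000", rng)
    return cf.build_session(cf.SessionConfig(), agent, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
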