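import numpy as np
import pytest

from arcpipe import task, simulate


@pytest.fixture(scope="session")
def design108():
    """The standard 108-trial counterbalanced design."""
    return task.generate_design(seed=1)


@pytest.fixture(scope="session")
def small_dataset(design108):
    """A small simulated cohort for fast model-level tests.

    Between-participant SDs are kept modest so that the sample of 8
    participants represents the group means well (recovery checks then
    probe the fit, not cohort sampling noise).
    """
    group = simulate.GroupParameters(
        beta_sd=(0.4, 0.4, 0.4, 0.6), alpha_sd=(0.05, 0.1)
    )
    return simulate.simulate_participants(group, 8, design=design108, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
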