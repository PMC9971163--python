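import numpy as np
import pandas as pd
import pytest

from srclearn.design import generate_trial_schedule, make_block_orders
from srclearn.perceptual import HGFParams, hgf_filter
from srclearn.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def designs():
    return make_block_orders()


@pytest.fixture(scope="session")
def schedule(designs):
    return generate_trial_schedule(designs[0], subject_id="S01", seed=7)


@pytest.fixture(scope="session")
def prior_mean_trajectory(schedule):
    return hgf_filter(schedule["u"].to_numpy(), HGFParams())


@pytest.fixture(scope="session")
def small_cohort():
    """Four HGF-generated subjects for smoke/pipeline tests."""
    return simulate_cohort(CohortSpec(n_subjects=4, seed=11))


@pytest.fixture(scope="session")
def full_cohort():
    """A 28-subject cohort at default generating conditions."""
    return simulate_cohort(CohortSpec(n_subjects=28, seed=1))
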