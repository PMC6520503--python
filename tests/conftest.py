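import numpy as np
import pytest
from hypothesis import settings

from reachgain import design_sim as ds

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp3_conditions():
    return ds.experiment_conditions(3)


@pytest.fixture(scope="session")
def small_cohort_gains(exp3_conditions):
    """A 6-subject value-manipulation gain table used by several fit tests."""
    subjects = ds.sample_subject_params(n_subjects=6, seed=42)
    gains = ds.simulate_gain_table(exp3_conditions, subjects,
                                   trials_per_cell=18, seed=43)
    return subjects, gains
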