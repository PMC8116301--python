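import numpy as np
import pytest

from glycomody import synth


@pytest.fixture(scope="session")
def default_cohort():
    return synth.generate_cohort(synth.CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_peak_table(default_cohort):
    return synth.cohort_to_peak_table(default_cohort, noise_cv=0.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
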