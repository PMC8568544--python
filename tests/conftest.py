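import numpy as np
import pytest

from oadcompare.simulate import SimulationConfig, make_paper_fixture, \
    simulate_cohort


@pytest.fixture(scope="session")
def paper_records():
    """Deterministic 1903-patient fixture with the published arm/city counts."""
    return make_paper_fixture()


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated cohort under the default (confounded) study conditions."""
    return simulate_cohort(SimulationConfig(seed=11), with_records=True)


@pytest.fixture(scope="session")
def sim_frames(sim_cohort):
    """(covariates, arms, outcomes) with plain integer row indices."""
    return (sim_cohort.covariates.reset_index(drop=True),
            sim_cohort.arms.reset_index(drop=True),
            sim_cohort.outcomes.reset_index(drop=True))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20211028)
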