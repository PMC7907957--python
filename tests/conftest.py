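import numpy as np
import pytest

import udn_triage as u


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-application cohort at the default study configuration."""
    return u.generate_cohort(u.default_config(n_total=300, seed=1))


@pytest.fixture(scope="session")
def cohort_5000():
    """A large cohort for marginal-recovery checks."""
    return u.generate_cohort(u.default_config(n_total=5000, seed=11))


@pytest.fixture(scope="session")
def corpus():
    return u.generate_phenotype_corpus(
        50, u.default_config().letter_params, np.random.default_rng(2)
    )


def make_app(**overrides) -> u.Application:
    """A minimal valid application for unit tests."""
    fields = dict(
        id="A1", submission_day=0, recorded_review_day=30, label="accepted",
        age_at_application=20.0, age_at_onset=10.0, duration=10.0,
        prior_visits=1, symptom_category="neurologic", letter="patient letter text",
    )
    fields.update(overrides)
    return u.Application(**fields)
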