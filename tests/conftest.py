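"""Shared fixtures: deterministic synthetic cohorts at several sizes."""

import pytest
from hypothesis import settings

import sciatica_triage as st

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screened_cohort():
    """One default screened cohort (n=609), canonical columns only."""
    return st.generate_cohort(st.GeneratorConfig(seed=3))


@pytest.fixture(scope="session")
def prepared_cohort(screened_cohort):
    """Screened cohort with scores, composite and characteristics appended."""
    return st.prepare_cohort(screened_cohort)


@pytest.fixture(scope="session")
def eligible_cohort(prepared_cohort):
    """The eligible (confidence >= 70%) analysis sample of the default cohort."""
    eligible, _ = st.filter_eligible(prepared_cohort)
    return eligible


@pytest.fixture(scope="session")
def large_cohort():
    """A large prepared eligible cohort for convergence checks (n ~ 84k)."""
    df = st.generate_cohort(st.GeneratorConfig(n_screened=120_000, seed=11))
    eligible, _ = st.filter_eligible(df)
    return st.prepare_cohort(eligible)
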