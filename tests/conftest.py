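import pytest

from ogtt_screen.cohort import GeneratorParams, attach_outcomes, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seeded mid-size cohort with outcomes, shared across tests."""
    params = GeneratorParams(n_subjects=800, seed=42)
    return attach_outcomes(generate_cohort(params), params)


@pytest.fixture(scope="session")
def study_cohort():
    """Default-parameter cohort at the study's sample size (n = 1031)."""
    params = GeneratorParams(n_subjects=1031, seed=0)
    return attach_outcomes(generate_cohort(params), params)
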