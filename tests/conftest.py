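import pytest

from fmt_rewire.synthetic_cohort import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (15 patients, 12 responders), shared."""
    return generate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def screening_cohort():
    """Balanced cohort with 10 donors and 10 patients per stratum."""
    return generate_cohort(
        SynthConfig(n_patients=20, responder_fraction=0.5, n_donor_samples=10, seed=3)
    )
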