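import pytest

from digitstat.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (258 subjects, injected overhand effect)."""
    return generate_cohort(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with the overhand effect switched off."""
    return generate_cohort(SyntheticConfig(seed=7, overhand_effect_d=0.0))
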