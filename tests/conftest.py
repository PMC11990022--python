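import pytest

from glycendo import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (95 HS / 49 controls), fixed seed."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """Large synthetic cohort for distribution-level checks."""
    return generate(SyntheticConfig(n_hs=4000, n_control=4000, seed=7))
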