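import pytest

from nlskit import SyntheticSpec, make_cohort


@pytest.fixture(scope="session")
def cohort_seed1():
    """Default planted-motif cohort, seed 1 (shared, read-only)."""
    return make_cohort(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def spec_seed1():
    return SyntheticSpec(seed=1)
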