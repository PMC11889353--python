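import numpy as np
import pytest

from phosmr import FixtureSpec, ScenarioConfig, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A scenario small enough for per-test replicate runs."""
    return ScenarioConfig(n_gwas=2000, n_small=100, n_reps=10, seed=7)


@pytest.fixture(scope="session")
def default_fixture_cohort():
    """One default synthetic cohort, shared across tests (read-only)."""
    return make_cohort(FixtureSpec(seed=11))
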