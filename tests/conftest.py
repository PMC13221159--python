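import numpy as np
import pytest

from lasap import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """100-participant cohort at desk scale (300 acoustic features)."""
    return generate_cohort(SyntheticConfig(n_participants=100, n_acoustic=300, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
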