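import numpy as np
import pytest

from wavetex import SyntheticCohortConfig, generate_feature_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240701)


@pytest.fixture(scope="session")
def null_feature_cohort():
    """Feature-level cohort with no class difference (fixed seed)."""
    return generate_feature_cohort(SyntheticCohortConfig(effect=0.0, seed=11))


@pytest.fixture(scope="session")
def separated_feature_cohort():
    """Feature-level cohort with a decisive 6-SD planted shift."""
    return generate_feature_cohort(SyntheticCohortConfig(effect=6.0, seed=12))
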