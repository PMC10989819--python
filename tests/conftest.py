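import numpy as np
import pytest

from micromarkers import AbundanceProfile, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default simulated cohort (100/100 samples, 200 features,
    20 planted markers, log-scale effect 1.0), shared across tests."""
    profile, metadata, truth = generate_cohort(CohortConfig(seed=1))
    return profile, metadata, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small, quick cohort for plumbing tests."""
    cfg = CohortConfig(n_case=30, n_control=30, n_features=40, n_markers=6,
                       effect_size=1.5, seed=7)
    profile, metadata, truth = generate_cohort(cfg)
    return profile, metadata, truth


@pytest.fixture
def tiny_profile():
    return AbundanceProfile(
        sample_ids=["s1", "s2"],
        feature_ids=["fa", "fb", "fc"],
        values=np.array([[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]]),
    )
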