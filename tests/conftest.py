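import numpy as np
import pytest

from gradconn.cohort import CohortConfig, make_cohort
from gradconn.pipeline import compute_feature_matrix


def small_config(**overrides) -> CohortConfig:
    """Reduced cohort for fast simulation-based tests."""
    defaults = dict(
        n_pos=10, n_neg=10, n_volumes=120, n_parcels=24,
        seed_parcels=(2, 3), mfg_parcel=7, phg_parcel=12,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return make_cohort(default_config, seed=7)


@pytest.fixture(scope="session")
def default_cohort_features(default_config, default_cohort):
    """Full-size (66 x 232) seed-to-parcel feature matrix for one cohort."""
    fm = compute_feature_matrix(default_cohort, default_config, seed=7)
    labels = np.array([r.group for r in default_cohort])
    return fm, labels
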