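import numpy as np
import pytest

from eegdem.features import FeatureConfig, build_feature_matrix
from eegdem.preprocess import segment_cohort
from eegdem.synth import CohortConfig, default_profiles, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """9 recordings (3 per class), 60 s at 500 Hz, fixed seed."""
    config = CohortConfig(
        profiles=tuple(default_profiles()),
        subjects_per_class=3,
        duration_s_range=(60.0, 60.0),
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Feature matrix of the small cohort: 27 epochs x 342."""
    epochs = segment_cohort(small_cohort, epoch_seconds=30.0,
                            overlap_fraction=0.5)
    return build_feature_matrix(epochs, FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
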