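import numpy as np
import pytest

from neurospect import CohortSpec, features_from_records, iter_cohort
from neurospect.pipeline import compute_feature_table
from neurospect.io import PipelineConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """Tiny cohort spec for fast structural tests."""
    return CohortSpec(n_per_class=2, n_channels=3, duration=10.0, fs=256.0, seed=11)


@pytest.fixture(scope="session")
def default_config():
    """The full default pipeline configuration (64 subjects per class)."""
    return PipelineConfig(seed=1234)


@pytest.fixture(scope="session")
def default_feature_table(default_config):
    """Features of the full default cohort (64/class, 300 s, 19 channels).

    Session-scoped because generating 192 full-size records dominates the
    suite's runtime; every consumer treats it as read-only.
    """
    return compute_feature_table(default_config)


@pytest.fixture(scope="session")
def quick_feature_table():
    """Features of a reduced cohort (16/class, 30 s, 3 channels) for tests
    that need class structure but not the full geometry."""
    spec = CohortSpec(n_per_class=16, n_channels=3, duration=30.0, fs=256.0, seed=77)
    return features_from_records(iter_cohort(spec))
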