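import numpy as np
import pytest

from voxelsvm.cohort import default_two_site_spec, generate_cohort


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale (16^3) two-site spec with the default study design."""
    return default_two_site_spec(seed=7, grid_shape=(16, 16, 16))


@pytest.fixture(scope="session")
def desk_cohort(desk_spec):
    return generate_cohort(desk_spec)


@pytest.fixture(scope="session")
def desk_features(desk_cohort):
    """Preprocessed features of the desk-scale cohort (shared, read-only)."""
    from voxelsvm.workflow import prepare_features

    feats, y, sites = prepare_features(desk_cohort)
    return feats, y, sites


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
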