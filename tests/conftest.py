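import numpy as np
import pytest

from fcdiff import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one strongly planted edge, shared across tests."""
    cfg = SyntheticConfig(
        n_group1=30,
        n_group2=30,
        n_rois=8,
        n_timepoints=200,
        planted_edges=[(0, 1, 0.5)],
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
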