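import numpy as np
import pytest

from jointica import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A compact cohort: quick to generate and decompose, still multimodal."""
    return SimConfig(n_subjects=40, n_rois=20, n_deep_rois=4, gm_features=300,
                     k_sources=3, seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_data():
    """Generator defaults at the study scale (90 subjects, 121 ROIs, k=4)."""
    return generate_dataset(SimConfig(k_sources=4, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
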