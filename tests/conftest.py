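import logging

import numpy as np
import pytest

import rvrfusion as rf

# the empty-selection fallback is exercised deliberately in several tests;
# keep the log quiet
logging.getLogger("rvrfusion.pipeline").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Three 300-voxel modalities, 10 true voxels each, n=120, planted R^2=0.5."""
    cfg = rf.SyntheticConfig(
        n_subjects=120,
        voxels_per_modality={"alff": 300, "gmv": 300, "fa": 300},
        n_true_voxels={"alff": 10, "gmv": 10, "fa": 10},
        seed=7,
    )
    return rf.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Small dataset with no score noise: predictions can reach the ceiling."""
    cfg = rf.SyntheticConfig(
        n_subjects=80,
        voxels_per_modality={"a": 120, "b": 120},
        n_true_voxels={"a": 10, "b": 10},
        noise_sd=0.2,
        planted_r2=None,
        score_noise_sd=0.0,
        seed=11,
    )
    return rf.generate_dataset(cfg)
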