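import numpy as np
import pytest

from atlas_sct.config import default_config, merge_config
from atlas_sct.image_core import Volume
from atlas_sct.phantom import PhantomConfig, make_subject


@pytest.fixture(scope="session")
def tiny_phantom_cfg() -> PhantomConfig:
    """Small, fast phantom grid for unit tests."""
    return PhantomConfig(shape=(48, 48, 32), spacing=(2.0, 2.0, 2.5))


@pytest.fixture(scope="session")
def tiny_subject(tiny_phantom_cfg):
    return make_subject(tiny_phantom_cfg, seed=5, subject_id="tiny_05")


@pytest.fixture(scope="session")
def fast_pipeline_cfg() -> dict:
    """Pipeline config with a light registration schedule for small grids."""
    return merge_config(default_config(), {
        "registration": {
            "grid_spacing_mm": 30.0,
            "pyramid_levels": 2,
            "iterations_per_level": [30, 10],
        },
        "bias": {"n_iter": 10},
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                tag="MR_WATER") -> Volume:
    return Volume(np.asarray(data, dtype=float), np.asarray(spacing),
                  np.asarray(origin), np.eye(3), tag)
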