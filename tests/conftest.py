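import numpy as np
import pytest

from aqua_ae.synth import SceneParams, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene_params():
    """Default-condition scenes at test scale."""
    return SceneParams(height=64, width=64, seed=900)


@pytest.fixture(scope="session")
def scene_batch(small_scene_params):
    """20 default scenes with their ground-truth boxes (session-cached)."""
    frames, box_lists = make_dataset(20, small_scene_params)
    return np.stack(frames), box_lists
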