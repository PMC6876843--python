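import warnings

import numpy as np
import pytest

from arenatrack.robustness import fixture_config
from arenatrack.synth import make_fixture
from arenatrack.tracker import run

# partial background stacks are expected on short clips
warnings.filterwarnings(
    "ignore", message="background stream ended before all stacks filled"
)


@pytest.fixture(scope="session")
def short_fixture():
    """20 s, 12-arena synthetic video with ground truth (rendered once)."""
    scene, rois, truth, frames = make_fixture(seed=7, duration_s=20.0)
    return scene, rois, truth, list(frames())


@pytest.fixture(scope="session")
def tracked_short_fixture(short_fixture):
    scene, rois, truth, frames = short_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run(frames, fixture_config(), rois=rois)
    return scene, rois, truth, frames, result


@pytest.fixture
def rng():
    return np.random.default_rng(0)
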