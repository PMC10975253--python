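import numpy as np
import pytest

from orchardcount.pipeline import PipelineConfig, count_flight
from orchardcount.simulator import (CameraRig, NOISE_PRESETS, SceneParams,
                                    generate_scene, simulate_flight)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240316)


@pytest.fixture(scope="session")
def small_scene():
    """5 trees x 10 fruits: the 50-fruit reference scene."""
    return generate_scene(SceneParams(fruits_per_tree=10), seed=7, n_trees=5)


@pytest.fixture(scope="session")
def clean_flight(small_scene):
    """Zero-noise pass over the 50-fruit scene."""
    return simulate_flight(small_scene, CameraRig(), speed=0.5,
                           noise=NOISE_PRESETS["none"], seed=11)


@pytest.fixture(scope="session")
def clean_result(clean_flight):
    return count_flight(clean_flight, PipelineConfig(seed=7))
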