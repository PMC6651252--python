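import numpy as np
import pytest

from bananagrade.synthetic import (
    DEFAULT_APPEARANCE,
    STAGES,
    SceneConfig,
    generate_scene,
)


@pytest.fixture(scope="session")
def scene_config() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def scenes_by_stage(scene_config):
    """One default scene per maturity stage, fixed seeds."""
    return {
        stage: generate_scene(scene_config, DEFAULT_APPEARANCE[stage], seed=11 + i)
        for i, stage in enumerate(STAGES)
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_rgb_patch(rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 256, size=(48, 48, 3), dtype=np.uint8)
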