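"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from icmscope import LocalizationModel, SceneConfig, analyze_field, generate_scene


@pytest.fixture(scope="session")
def restricted_model():
    return LocalizationModel(pattern="restricted")


@pytest.fixture(scope="session")
def small_restricted_scene(restricted_model):
    """~25 restricted cells, every cell adhesin-marked, default noise."""
    cfg = SceneConfig(n_cells=25, field_shape=(512, 512), adhesin_fraction=1.0,
                      seed=42)
    field_img, truth = generate_scene(cfg, restricted_model)
    return cfg, restricted_model, field_img, truth


@pytest.fixture(scope="session")
def small_restricted_analysis(small_restricted_scene):
    _, _, field_img, _ = small_restricted_scene
    return analyze_field(field_img)


@pytest.fixture(scope="session")
def small_nonrestricted_scene():
    cfg = SceneConfig(n_cells=35, field_shape=(640, 640), seed=5)
    model = LocalizationModel(pattern="nonrestricted")
    field_img, truth = generate_scene(cfg, model)
    return cfg, model, field_img, truth


@pytest.fixture(scope="session")
def small_nonrestricted_analysis(small_nonrestricted_scene):
    _, _, field_img, _ = small_nonrestricted_scene
    return analyze_field(field_img)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
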