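"""Shared fixtures: small rendered scenes and trained models.

The "small" fixtures run the full pipeline at 768 x 768 px (50 x 50 µm)
with ~12 cells per field so unit tests stay fast; the acceptance suite
builds the full-scale study conditions separately.
"""

from __future__ import annotations

import pytest

from caulotype.config import OpticsConfig, RunConfig
from caulotype.pipeline import annotate_image, train_models_from_dataset
from caulotype.render import render
from caulotype.scenes import build_scene

SMALL_SHAPE = (768, 768)


@pytest.fixture(scope="session")
def small_optics() -> OpticsConfig:
    return OpticsConfig(frame_shape=SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_config(small_optics) -> RunConfig:
    return RunConfig(optics=small_optics)


@pytest.fixture(scope="session")
def small_train_pairs(small_optics):
    presets = ["exponential"] * 4 + ["c_lim", "p_lim"]
    return [
        render(build_scene(p, 12, small_optics, seed=100 + i))
        for i, p in enumerate(presets)
    ]


@pytest.fixture(scope="session")
def small_models(small_train_pairs, small_config):
    models, report = train_models_from_dataset(small_train_pairs, small_config, seed=11)
    models.training_report = report
    return models


@pytest.fixture(scope="session")
def held_out_frame(small_optics):
    scene = build_scene("test_default", 14, small_optics, seed=900)
    image, truth = render(scene)
    return image, truth


@pytest.fixture(scope="session")
def annotated_held_out(held_out_frame, small_models, small_config):
    image, truth = held_out_frame
    return annotate_image(image, small_models, small_config), truth


@pytest.fixture(scope="session")
def blank_frame(small_optics):
    from caulotype.scenes import SceneSpec

    scene = SceneSpec(cells=[], optics=small_optics, seed=5, condition_preset="blank")
    return render(scene)
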