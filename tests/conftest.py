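"""Shared fixtures: desk-scale phantom data and trained segmentation models.

Training the desk transformer is by far the most expensive step, so the
three seeded models (and the phantom cohorts they are scored on) are built
once per session and shared by every test that needs them.
"""

import numpy as np
import pytest

from octdls.data import easy_desk_cohort, training_set_from_eyes
from octdls.preprocess import PreprocessConfig
from octdls.vit import TrainConfig, ViTConfig, train

TRAIN_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def desk_pre_config():
    return PreprocessConfig.desk()


@pytest.fixture(scope="session")
def easy_train_set(desk_pre_config):
    eyes = easy_desk_cohort(5, 4, seed=101)
    vit_set, unet_set = training_set_from_eyes(eyes, desk_pre_config, seed=7)
    return vit_set, unet_set


@pytest.fixture(scope="session")
def easy_val_set(desk_pre_config):
    eyes = easy_desk_cohort(3, 2, seed=202)
    vit_set, unet_set = training_set_from_eyes(eyes, desk_pre_config, seed=8)
    return vit_set, unet_set


@pytest.fixture(scope="session")
def easy_cohort():
    """Held-out eyes for end-to-end eye-level classification."""
    return easy_desk_cohort(5, 6, seed=303)


@pytest.fixture(scope="session")
def trained_desk_models(easy_train_set):
    """Three desk-recipe transformer segmenters trained from different seeds."""
    vit_set, _ = easy_train_set
    models = []
    for seed in TRAIN_SEEDS:
        model, _ = train(vit_set, ViTConfig(), TrainConfig.desk_recipe(seed=seed))
        models.append(model)
    return models
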