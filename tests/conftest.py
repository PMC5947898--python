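import warnings

import numpy as np
import pytest

from pulsepatch.joint_align import CascadeConfig, train_cascade
from pulsepatch.patch_mesh import track_patches
from pulsepatch.skin_map import train_skin_model
from pulsepatch.synthetic_scene import (
    DetectionTaskConfig,
    SceneConfig,
    SkinTrainingConfig,
    generate_detection_task,
    generate_scene,
    generate_skin_training_set,
)

# training settings for the toy joint-detection task; weak (depth-2) trees
# keep negatives alive for more cascade stages, giving a graded score
TOY_CASCADE = CascadeConfig(
    tree_depth=2, n_stages=12, pass_rate=0.995, n_features=192, seed=0
)


@pytest.fixture(scope="session")
def default_scene():
    """Stock 30-s synthetic clip (72 bpm) with occluders and unstable patches."""
    return generate_scene(SceneConfig(hr_true=72.0, seed=7))


@pytest.fixture(scope="session")
def default_track_set(default_scene):
    stack, truth = default_scene
    return track_patches(stack, truth.landmark_track)


@pytest.fixture(scope="session")
def skin_model():
    """Skin histogram model trained on the synthetic 78-image set."""
    images, masks = generate_skin_training_set(SkinTrainingConfig(seed=99))
    return train_skin_model(images, masks)


@pytest.fixture(scope="session")
def detection_task():
    return generate_detection_task(DetectionTaskConfig(seed=0, n_neg=600))


@pytest.fixture(scope="session")
def detector(detection_task):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_cascade(
            detection_task.positives, detection_task.negatives, TOY_CASCADE
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
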