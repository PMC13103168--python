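"""Shared fixtures: the desk-scale trained GAN and held-out phantom sets.

The session-scoped model is trained once (999 steps on 200 frontal phantoms
at 64x64, compact width) and reused by every integration-level test.
"""

import pytest

from ganscreen.gan import GanConfig, build_models, train_gan
from ganscreen.synthetic import PhantomSpec, ViewLabel, generate_dataset

# desk-scale study conditions (see docs/methods.md)
TRAIN_SEED = 0
DATA_SEED = 42
HELDOUT_SEED = 777
CALIBRATION_SEED = 555
N_TRAIN = 200
RESOLUTION = 64


def desk_gan_config(seed: int = TRAIN_SEED) -> GanConfig:
    return GanConfig(resolution=RESOLUTION, base_feature_maps=16,
                     batch_size=16, train_steps=999, seed=seed)


def phantom_base(res: int = RESOLUTION) -> PhantomSpec:
    return PhantomSpec(view_class=ViewLabel.FRONTAL, resolution=res)


@pytest.fixture(scope="session")
def trained():
    """(models, trace) after full 999-step training on frontal phantoms."""
    cfg = desk_gan_config()
    images = generate_dataset(N_TRAIN, 0, phantom_base(), DATA_SEED)
    models, trace = train_gan(build_models(cfg), images, cfg)
    return models, trace


@pytest.fixture(scope="session")
def heldout_set():
    """20 frontal + 20 lateral phantoms unseen during training."""
    return generate_dataset(20, 20, phantom_base(), HELDOUT_SEED)


@pytest.fixture(scope="session")
def calibration_set():
    """Labeled split for baseline threshold selection (disjoint seed)."""
    return generate_dataset(20, 20, phantom_base(), CALIBRATION_SEED)
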