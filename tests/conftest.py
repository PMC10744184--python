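import numpy as np
import pytest

from virtualgrid import (NoiseParams, desk_config, make_phantom,
                         make_training_pairs, noise_grid, train_gan)

TRAIN_NOISE_ALPHAS = [2.0, 4.0, 8.0]
TRAIN_NOISE_BETAS = [4.0, 8.0]
TEST_NOISE = NoiseParams(4.0, 8.0)
PHANTOM_KW = dict(height=256, width=256, pixel_size=0.5, n_calcifications=3)


@pytest.fixture(scope="session")
def phantom_scene():
    return make_phantom(seed=1, **PHANTOM_KW)


@pytest.fixture(scope="session")
def desk_model():
    """One 20-epoch desk-scale training run shared across the suite.

    Two phantom scenes x a 3x2 grid of noise levels x 16 patches of 64 px
    give 192 training pairs; the best-validation generator is returned.
    """
    cleans = [make_phantom(seed=s, **PHANTOM_KW).primary for s in (1, 2)]
    grid = noise_grid(TRAIN_NOISE_ALPHAS, TRAIN_NOISE_BETAS)
    config = desk_config(epochs=20, seed=0)
    pairs = make_training_pairs(cleans, grid, config, seed=11)
    return train_gan(pairs, config)
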