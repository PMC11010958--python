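import numpy as np
import pytest

from endovit import swin, vit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def image_batch(rng):
    """Small valid (B, H, W, C) image batch in [0, 1]."""
    return rng.random((3, 16, 16, 3))


@pytest.fixture
def tiny_vit_cfg():
    return vit.ViTConfig(image_size=16, patch_size=8, depth=2, hidden_size=32,
                         mlp_size=64, num_heads=4, num_classes=3)


@pytest.fixture
def tiny_vit_params(tiny_vit_cfg, rng):
    return vit.init_vitcol_params(tiny_vit_cfg, rng)


@pytest.fixture
def tiny_swin_cfg():
    return swin.SwinConfig(image_size=16, patch_size=4, embed_dim=8,
                           depths=(2, 2), heads=(2, 2), window_size=2)


@pytest.fixture
def tiny_swin_params(tiny_swin_cfg, rng):
    return swin.init_puts_params(tiny_swin_cfg, rng)
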