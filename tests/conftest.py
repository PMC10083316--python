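import numpy as np
import pytest
from dataclasses import replace

from bafnet import LeafGenConfig, generate_leaf


@pytest.fixture(scope="session")
def leaf_batch_64():
    """Eight synthetic 64x64 leaf image/mask pairs (the smoke-training set)."""
    cfg = LeafGenConfig(image_size=64, seed=0)
    imgs, masks = [], []
    for i in range(8):
        im, mk = generate_leaf(replace(cfg, seed=i))
        imgs.append(im)
        masks.append(mk)
    return np.stack(imgs), np.stack(masks)


def to_float64(module):
    """Cast a module's parameters in place for tight-tolerance oracle checks."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    return module
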