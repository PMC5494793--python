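import numpy as np
import pytest

from mammocad import ImageGrid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """64x64 8-bit-range random image."""
    return ImageGrid(rng.integers(0, 256, (64, 64)).astype(float), bit_depth=8)


@pytest.fixture
def dataset_tree(tmp_path):
    """Minimal valid 12-leaf dataset tree with 2 images per leaf."""
    from mammocad import TISSUE_LABELS, HEALTH_LABELS, save_image

    rng = np.random.default_rng(0)
    root = tmp_path / "data"
    for t in TISSUE_LABELS:
        for h in HEALTH_LABELS:
            leaf = root / t / h
            leaf.mkdir(parents=True)
            for i in range(2):
                save_image(rng.integers(0, 256, (32, 32)).astype(float),
                           leaf / f"img_{i}.png")
    return root
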