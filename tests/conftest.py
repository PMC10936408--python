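import numpy as np
import pytest

from beadframe.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A compact textured phantom shared by stitching/alignment tests."""
    cfg = PhantomConfig(n_tiles=(4, 4), tile_size_px=96, n_slices=8,
                        n_beads=60, texture_amplitude=40.0, n_blobs=2,
                        blob_amplitude=700.0)
    return generate_phantom(cfg, seed=11)


@pytest.fixture(scope="session")
def default_phantom():
    """The default-geometry phantom (8x8 tiles, 20 slices, ~30 beads/slice)."""
    return generate_phantom(PhantomConfig(), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
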