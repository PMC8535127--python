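import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def noise_image(rng):
    """64×64 iid uniform(0,255) image."""
    return rng.uniform(0.0, 255.0, size=(64, 64))


@pytest.fixture
def small_noise(rng):
    """12×12 iid uniform(0,255) image, small enough for brute-force oracles."""
    return rng.uniform(0.0, 255.0, size=(12, 12))


@pytest.fixture
def constant_image():
    return np.full((10, 10), 42.0)


@pytest.fixture
def png_tree(tmp_path):
    """Write a tiny two-class PNG tree and return its root."""
    import imageio.v3 as iio

    rng = np.random.default_rng(5)
    for label in ("alpha", "beta"):
        d = tmp_path / "data" / label
        d.mkdir(parents=True)
        for i in range(3):
            img = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
            iio.imwrite(d / f"{label}_{i}.png", img)
    return tmp_path / "data"
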