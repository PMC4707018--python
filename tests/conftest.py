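import numpy as np
import pytest

from vesselab.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vessel_image():
    """A moderately cluttered synthetic vessel image with ground truth."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def clean_vessel_image():
    """A clutter-, texture- and noise-free vessel image with ground truth."""
    return generate(
        SyntheticSpec(clutter_density=0.0, texture_amp=0.0, noise_sigma=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def rectangle_fixture():
    """Two-constant-region image (0.2 field, 0.8 rectangle) and its truth."""
    img = np.full((64, 64), 0.2)
    truth = np.zeros((64, 64), bool)
    truth[20:44, 14:50] = True
    img[truth] = 0.8
    return img, truth


def mask_agreement(a, b):
    """Fraction of pixels on which two 2-region partitions agree (label-swap
    invariant)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    m = (a == b).mean()
    return max(m, 1.0 - m)
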