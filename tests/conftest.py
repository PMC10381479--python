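import numpy as np
import pytest
from scipy.ndimage import binary_fill_holes, gaussian_filter

from sulcuseg import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_blob(rng, shape=(48, 48), smooth=3.0, frac=0.2):
    """Seeded single-component, hole-free random blob mask."""
    from skimage.measure import label

    noise = gaussian_filter(rng.normal(size=shape), smooth)
    mask = noise > np.quantile(noise, 1.0 - frac)
    lab = label(mask.astype(int), connectivity=2)
    if lab.max() == 0:
        mask = np.zeros(shape, dtype=bool)
        mask[shape[0] // 2, shape[1] // 2] = True
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    mask = lab == (1 + int(np.argmax(sizes)))
    return binary_fill_holes(mask)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom shared by pipeline-level tests."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=11, speckle_sigma=0.0, blur_sigma=0.0))
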