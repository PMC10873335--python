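import numpy as np
import pytest

from sparsect.phantoms import PhantomImage, sample_chest_phantom


@pytest.fixture(scope="session")
def chest64():
    """One seeded 64-px chest phantom with its ROI layout."""
    return sample_chest_phantom(seed=11, size=64)


@pytest.fixture(scope="session")
def chest128():
    return sample_chest_phantom(seed=11, size=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_disc(size: int, value: float, radius_frac: float = 0.35,
              background: float = -1000.0) -> PhantomImage:
    """Hard-edged centered disc phantom."""
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size, dtype=float),
                             np.arange(size, dtype=float))
    px = np.where(np.hypot(cols - c, rows - c) <= radius_frac * size,
                  value, background)
    return PhantomImage(px, 450.0 / size)


def make_smooth_disc(size: int, amplitude: float = 1000.0,
                     background: float = -1000.0) -> PhantomImage:
    """Rotationally symmetric disc with a smooth (logistic) edge, so that
    grid discretization does not break the symmetry of its projections."""
    c = (size - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(size, dtype=float),
                             np.arange(size, dtype=float))
    r = np.hypot(cols - c, rows - c)
    px = background + amplitude / (1.0 + np.exp((r - 0.3 * size) / 3.0))
    return PhantomImage(px, 450.0 / size)
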