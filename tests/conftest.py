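import numpy as np
import pytest
from hypothesis import settings

from lungtex import (
    CTVolume,
    PhantomParams,
    QuantisationScheme,
    QuantisedVolume,
    ROIMask,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_quantised(levels: np.ndarray, mask: np.ndarray | None = None,
                   n_levels: int = 16) -> QuantisedVolume:
    """Wrap an integer level array (1..n_levels) as a QuantisedVolume."""
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    scheme = QuantisationScheme(n_levels, np.linspace(0, n_levels, n_levels + 1), "test")
    lv = np.where(mask, levels, 0)
    return QuantisedVolume(lv, ROIMask(mask, (1.0, 1.0, 1.0)), scheme)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_phantom_params():
    """Scaled-down phantom used where many volumes are generated."""
    return PhantomParams(shape=(8, 24, 24), spacing=(1.0, 1.0, 2.5))


@pytest.fixture
def random_volume(rng):
    return CTVolume(rng.uniform(0, 300, size=(6, 10, 10)), (1.0, 1.0, 2.5))
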