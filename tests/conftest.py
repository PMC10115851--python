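import numpy as np
import pytest

from vibe.core import Geometry, Volume
from vibe.phantom import PhantomSpec, make_atlas, make_subject


@pytest.fixture(scope="session")
def default_atlas():
    return make_atlas(PhantomSpec())


@pytest.fixture(scope="session")
def posed_subject():
    """A posed, inflated, noisy subject with its analytic truth."""
    spec = PhantomSpec(translation_mm=(10.0, -7.0, 6.0), rotation_deg=(5.0, -4.0, 6.0),
                       inflation=1.08, seed=3)
    return make_subject(spec) + (spec,)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                direction=np.eye(3)):
    return Volume(np.asarray(data, dtype=float),
                  Geometry.from_matrices(spacing, origin, direction))


@pytest.fixture
def unit_volume(rng):
    return make_volume(rng.normal(50, 10, size=(12, 11, 10)))
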