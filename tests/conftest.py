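"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest

from lungmotion import densitometry as dens
from lungmotion import motionography as motion
from lungmotion.phantom import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def default_pair():
    """Default dome phantom (96³ at 2 mm, 10 mm dome descent, noisy)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(48, 48, 48), spacing=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def small_pair(small_spec):
    """Coarse dome phantom for cheap unit tests (48³ at 4 mm)."""
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def default_ctx(default_pair):
    return motion.NormalizationContext(
        v_in=dens.lung_volume(default_pair.inspiration_seg),
        v_ex=dens.lung_volume(default_pair.expiration_seg),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
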