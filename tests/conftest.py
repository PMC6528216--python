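import numpy as np
import pytest

import otomorph as om
from otomorph.grids import BinaryMask


@pytest.fixture(scope="session")
def default_spec():
    return om.PhantomSpec()


@pytest.fixture(scope="session")
def spiral_phantom(default_spec):
    """Standard spiral duct phantom at 10 μm spacing, with ground truth."""
    return om.make_spiral_duct_phantom(default_spec)


@pytest.fixture(scope="session")
def small_spiral_spec():
    """A compact spiral for fast unit tests."""
    return om.PhantomSpec(
        n_turns=1.5,
        base_radius_um=800.0,
        apex_radius_um=400.0,
        pitch_um=300.0,
        tube_radius_base_um=90.0,
        tube_radius_apex_um=60.0,
        voxel_spacing_um=10.0,
    )


@pytest.fixture(scope="session")
def small_spiral_phantom(small_spiral_spec):
    return om.make_spiral_duct_phantom(small_spiral_spec)


@pytest.fixture(scope="session")
def registration_fixture():
    """(volume, truth transform, section) for the registration tests."""
    return om.make_registration_fixture()


def make_ball_mask(radius_vox: int, spacing: float = 1.0, pad: int = 3) -> BinaryMask:
    n = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    x, y, z = np.mgrid[0:n, 0:n, 0:n]
    ball = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    return BinaryMask(mask=ball, spacing_um=spacing)


def random_blob_mask(rng: np.random.Generator, n: int = 20) -> BinaryMask:
    """A random union of a few balls plus voxel noise, for morphology
    property tests."""
    mask = np.zeros((n, n, n), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        c = rng.uniform(4, n - 4, size=3)
        r = rng.uniform(2, 5)
        x, y, z = np.mgrid[0:n, 0:n, 0:n]
        mask |= (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r * r
    mask |= rng.random((n, n, n)) < 0.02
    return BinaryMask(mask=mask, spacing_um=1.0)
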