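import numpy as np
import pytest

from smrirt import Mask, PhantomParams, ScalarMap, VolumeGrid, generate_phantom

# small test profile: 144 mm box at 2 mm, brain that still fits the
# default tumor geometry; properties under test are scale-free
SMALL_PARAMS = PhantomParams(
    clinical_shape=(72, 72, 72),
    clinical_spacing=(2.0, 2.0, 2.0),
    brain_semiaxes=(58.0, 64.0, 54.0),
)


@pytest.fixture
def unit_grid():
    return VolumeGrid((10, 10, 10), (1.0, 1.0, 1.0))


@pytest.fixture
def smri_grid():
    return VolumeGrid((8, 8, 6), (4.4, 4.4, 5.6))


@pytest.fixture(scope="session")
def noiseless_truth():
    """Shared noiseless small phantom (closed-form fold field)."""
    p = PhantomParams(
        clinical_shape=SMALL_PARAMS.clinical_shape,
        clinical_spacing=SMALL_PARAMS.clinical_spacing,
        brain_semiaxes=SMALL_PARAMS.brain_semiaxes,
        noise_cv=0.0, seed=11)
    return generate_phantom(p)


def random_mask(grid: VolumeGrid, rng, p: float = 0.3, label: str = "m") -> Mask:
    return Mask(grid, rng.random(grid.shape) < p, label)


def random_grid(rng, max_n: int = 14) -> VolumeGrid:
    shape = tuple(int(n) for n in rng.integers(4, max_n + 1, 3))
    spacing = tuple(float(s) for s in rng.uniform(0.5, 6.0, 3))
    origin = tuple(float(o) for o in rng.uniform(-20, 20, 3))
    return VolumeGrid(shape, spacing, origin)
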