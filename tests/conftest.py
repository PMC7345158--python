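import numpy as np
import pytest

from chemotex import run_synthetic_study
from chemotex.image_io import GrayPatch


def random_patch(rng: np.random.Generator, side: int, gray_levels: int) -> GrayPatch:
    return GrayPatch(
        pixels=rng.integers(0, gray_levels, size=(side, side)),
        gray_levels=gray_levels,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240609)


@pytest.fixture(scope="session")
def synthetic_study():
    """One full pipeline run shared by the slower end-to-end tests:
    20 images per phenotype at 300x300, master seed 1, offset (10, 0)."""
    return run_synthetic_study(n_images_per_group=20, seed=1, height=300, width=300)
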