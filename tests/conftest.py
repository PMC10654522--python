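import numpy as np
import pytest

import riverconnect as rc


@pytest.fixture(scope="session")
def kernel_14m():
    """7x7 kernel for a 14 m SDD species on a 5 m grid (decay ~0.19)."""
    return rc.build_kernel_from_sdd(14, 5, 0.95)


@pytest.fixture(scope="session")
def kernel_019():
    """Kernel built from the rounded decay 0.19, radius 3, 5 m cells."""
    return rc.build_kernel(0.19, 5, 3)


@pytest.fixture()
def two_singles():
    """Two single-cell patches with centres 2 cells (10 m) apart."""
    habitat = rc.two_patch_landscape(1, 1, 5)
    return habitat, rc.label_patches(habitat)


def random_landscape(seed: int, shape=(40, 40), n=8):
    spec = rc.LandscapeSpec.random(shape, n, seed=seed)
    return rc.random_blob_landscape(spec)


def unnormalized_kernel_sum(decay: float, cell_size: float, radius: int) -> float:
    """Independent scalar computation of the pre-normalisation kernel sum."""
    import math

    total = 0.0
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            total += (1 - decay) ** (cell_size * math.hypot(dr, dc))
    return total
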