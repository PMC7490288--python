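"""Shared fixtures: coarse phantoms for fast unit tests.

The coarse grid keeps the default 343 x 343 x 155 mm field of view at a
2x-coarser voxel pitch so the same mm-scale geometry is realizable while
volumes stay small.
"""

import numpy as np
import pytest

from pvcprop.grids import GridSpec
from pvcprop.phantom import (
    Parcellation,
    RegionSpec,
    assign_truth,
    build_attenuation,
    build_phantom,
)
from pvcprop.simulate import gaussian_blur


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec((64, 64, 32), (5.364, 5.364, 4.85))


@pytest.fixture(scope="session")
def hc_parc(small_grid):
    return build_phantom("HC", small_grid, seed=1)


@pytest.fixture(scope="session")
def ad_parc(small_grid):
    return build_phantom("AD", small_grid, seed=1)


@pytest.fixture(scope="session")
def hc_truth(hc_parc):
    return assign_truth(hc_parc, "HC")


@pytest.fixture(scope="session")
def hc_mu(hc_parc):
    return build_attenuation(hc_parc)


@pytest.fixture(scope="session")
def hc_blurred(hc_truth, small_grid):
    """Noiseless matched-blur observation (7 mm Gaussian) of the HC truth."""
    return gaussian_blur(hc_truth.values, 7.0, small_grid)


def make_toy_parcellation(shape=(40, 16, 16), voxel=(2.0, 2.0, 2.0), values=(2.0, 1.0, 0.5)):
    """Slab phantom: len(values) x-slabs inside a padded box, for oracle tests."""
    grid = GridSpec(shape, voxel)
    labels = np.zeros(shape, dtype=np.int16)
    n = len(values)
    pad = 6
    width = (shape[0] - 2 * pad) // n
    regions = []
    for k in range(n):
        sl = slice(pad + k * width, pad + (k + 1) * width)
        labels[sl, 4:-4, 4:-4] = k + 1
        regions.append(RegionSpec(k + 1, f"slab{k + 1}", "GM", "midline", {"HC": values[k]}))
    parc = Parcellation(grid, labels, regions)
    truth = np.zeros(shape)
    for k, v in enumerate(values):
        truth[labels == k + 1] = v
    return parc, truth
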