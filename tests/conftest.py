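"""Shared fixtures and independent oracles.

The oracles here are deliberately written against dense arrays with scipy /
scikit-image primitives so they stay independent of the package's streamed
implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import euler_number

from vesselgraph.volume_store import VoxelGrid

S26 = np.ones((3, 3, 3), dtype=bool)
S6 = ndimage.generate_binary_structure(3, 1)


def topology_counts(vol: np.ndarray):
    """(foreground 26-components, background 6-components, Euler characteristic)."""
    vol = np.asarray(vol, dtype=bool)
    fg = ndimage.label(vol, structure=S26)[1]
    bg = ndimage.label(np.pad(~vol, 1, constant_values=True), structure=S6)[1]
    eu = euler_number(vol, connectivity=3)
    return fg, bg, eu


def oracle_is_simple(window: np.ndarray) -> bool:
    """Brute force: does deleting the centre of the 3x3x3 pattern keep all
    three topology counts of the isolated pattern unchanged?"""
    window = np.asarray(window, dtype=bool)
    assert window.shape == (3, 3, 3) and window[1, 1, 1]
    after = window.copy()
    after[1, 1, 1] = False
    return topology_counts(window) == topology_counts(after)


def brute_force_surface(vol: np.ndarray) -> np.ndarray:
    """Linear indices of foreground voxels with a background 26-neighbor."""
    vol = np.asarray(vol, dtype=bool)
    padded = np.pad(vol, 1, constant_values=False)
    mn = ndimage.minimum_filter(padded.astype(np.uint8), size=3)[1:-1, 1:-1, 1:-1]
    return np.flatnonzero((vol & (mn == 0)).ravel())


def random_blob(rng: np.random.Generator, n: int, sigma: float = 2.5,
                quantile: float = 0.75) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.random((n, n, n)), sigma)
    return field > np.quantile(field, quantile)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_line_grid():
    arr = np.zeros((5, 5, 12), dtype=bool)
    arr[2, 2, 1:11] = True
    return VoxelGrid.from_array(arr)
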