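"""Shared fixtures: tiny geometries, grids and a dense-matrix projector oracle."""

import numpy as np
import pytest

from ctfr.geometry import (
    AttenuationImage,
    ImageGrid,
    Sinogram,
    default_grid,
    make_geometry,
)
from ctfr.projector import forward_project


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_geometry():
    """20 views over 360°, 24 bins — small enough for dense oracles."""
    return make_geometry(
        n_views=20, angular_range=360.0, n_bins=24,
        source_to_detector=100.0, center_to_detector=40.0,
        detector_extent=60.0)


@pytest.fixture
def limited_geometry():
    """Limited-angle variant: 197.88° orbit."""
    return make_geometry(
        n_views=20, angular_range=197.88, n_bins=24,
        source_to_detector=100.0, center_to_detector=40.0,
        detector_extent=60.0)


@pytest.fixture
def tiny_grid(tiny_geometry):
    return default_grid(tiny_geometry, 16)


def dense_matrix(geometry, grid) -> np.ndarray:
    """Build G explicitly by projecting unit-impulse images column by column."""
    n_pix = grid.n_rows * grid.n_cols
    n_ray = geometry.n_views * geometry.n_bins
    G = np.zeros((n_ray, n_pix))
    for j in range(n_pix):
        impulse = np.zeros(n_pix)
        impulse[j] = 1.0
        img = AttenuationImage(grid=grid, values=impulse.reshape(grid.shape))
        G[:, j] = forward_project(img, geometry).values.ravel()
    return G


@pytest.fixture
def sino_of(tiny_geometry):
    def make(values):
        return Sinogram(geometry=tiny_geometry, values=values)
    return make
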