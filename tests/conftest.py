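"""Shared fixtures: synthetic scenes and simple toy graphs."""

from __future__ import annotations

import numpy as np
import pytest

from ditchsdm import SceneConfig, build_scene, derive_covariates, rescale_covariates
from ditchsdm.grids import Grid
from ditchsdm.network import build_graph


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 synthetic catchment (seed 5), shared across read-only tests."""
    return build_scene(SceneConfig(grid_shape=(96, 96), seed=5))


@pytest.fixture(scope="session")
def small_table(small_scene):
    """Rescaled covariate table for the small scene."""
    return rescale_covariates(derive_covariates(small_scene))


@pytest.fixture(scope="session")
def medium_scene():
    """A 256x256 catchment used for recovery experiments (seed 5)."""
    return build_scene(SceneConfig(grid_shape=(256, 256), seed=5))


@pytest.fixture(scope="session")
def medium_table(medium_scene):
    return rescale_covariates(derive_covariates(medium_scene))


def path_graph_mask(n_cells: int, cell_size: float = 2.0):
    """A 1-row network mask of n_cells ditch cells (a path graph)."""
    mask = Grid(np.ones((1, n_cells)), cell_size=cell_size)
    return mask


@pytest.fixture()
def path_graph():
    """A 12-node path graph with 2 m orthogonal edges."""
    return build_graph(path_graph_mask(12), outlet=(0, 0))


@pytest.fixture()
def long_path_graph():
    """A 500-node path graph (1 km of network at 2 m cells)."""
    return build_graph(path_graph_mask(500), outlet=(0, 0))
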