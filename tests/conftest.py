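"""Shared fixtures: tiny monolayer geometries and meshes built at test time."""

import numpy as np
import pytest

from woundsim.geometry import (
    MonolayerSpec,
    build_voronoi_monolayer,
    excise_wound,
    extrude_to_wedges,
    generate_seeds,
)


class MiniMesh:
    """Bare element container for single-element finite-element checks."""

    def __init__(self, nodes, elements):
        self.nodes = np.asarray(nodes, dtype=float)
        self.elements = np.asarray(elements, dtype=np.int64)
        self.n_nodes = len(self.nodes)


@pytest.fixture
def unit_wedge():
    """One wedge on the unit triangle, unit height."""
    nodes = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 0, 1], [0, 1, 1]]
    return MiniMesh(nodes, [[0, 1, 2, 3, 4, 5]])


@pytest.fixture(scope="session")
def quad_spec():
    return MonolayerSpec(domain_side=60.0, mean_cell_diameter=26.0, thickness=10.0)


@pytest.fixture(scope="session")
def quad_geom(quad_spec):
    """Four congruent square cells from seeds at the quadrant centres."""
    seeds = np.array([[15.0, 15.0], [45.0, 15.0], [15.0, 45.0], [45.0, 45.0]])
    return build_voronoi_monolayer(quad_spec, seeds)


@pytest.fixture(scope="session")
def quad_mesh(quad_geom):
    return extrude_to_wedges(quad_geom, z0=1e-3)


@pytest.fixture(scope="session")
def small_geom():
    """~12-cell monolayer with a one-cell wound."""
    spec = MonolayerSpec(domain_side=90.0, wound_target_area=400.0, rng_seed=3)
    geom = build_voronoi_monolayer(spec, generate_seeds(spec))
    return excise_wound(geom, spec.wound_target_area)


@pytest.fixture(scope="session")
def small_mesh(small_geom):
    return extrude_to_wedges(small_geom, z0=1e-3)


@pytest.fixture(scope="session")
def default_geom():
    """Full-scale default tessellation (301 seeds, 400 μm square)."""
    spec = MonolayerSpec(rng_seed=1, wound_target_area=3136.0)
    geom = build_voronoi_monolayer(spec, generate_seeds(spec))
    return excise_wound(geom, spec.wound_target_area)
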