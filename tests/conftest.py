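"""Shared fixtures: coarse geometries and cached FE artifacts.

FE-backed fixtures use a deliberately coarse cross-section so the whole
suite stays fast; the acceptance tests run the full default configuration
separately.
"""

import numpy as np
import pytest

from toothmor import (
    GeometrySpec,
    Mesh,
    ParameterGrid,
    SolverOptions,
    build_toy_mesh,
    default_materials,
    generate_fe_snapshots,
)

COARSE_SPEC = GeometrySpec(
    root_radius=0.9, bone_outer_radius=1.8, crown_height=0.6, element_size=0.18
)


@pytest.fixture(scope="session")
def coarse_mesh():
    return build_toy_mesh(COARSE_SPEC)


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def solver_opts():
    return SolverOptions()


@pytest.fixture(scope="session")
def coarse_fe_tensor(coarse_mesh, materials, solver_opts):
    """2x2 FE snapshot tensor on the coarse mesh (4 quick solves)."""
    grid = ParameterGrid.uniform(50.0, 200.0, 2)
    return generate_fe_snapshots(coarse_mesh, materials, grid, solver_opts)


def make_square_mesh(n=4, size=1.0):
    """Structured unit-square mesh (single region) for patch testing."""
    xs = np.linspace(0.0, size, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel()], axis=-1)
    idx = np.arange((n + 1) ** 2).reshape(n + 1, n + 1)
    els = []
    for i in range(n):
        for j in range(n):
            a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
            els += [(a, b, c), (a, c, d)]
    return (
        Mesh(
            node_coords=coords,
            elements=np.asarray(els, dtype=np.int64),
            region_tag=np.zeros(len(els), dtype=np.int64),
            boundary_sets={"FIXED": idx[:, 0].copy(), "LOAD": idx[:, -1].copy()},
        ),
        idx,
    )
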