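"""Shared fixtures: small meshes, parcellations, and planted cohorts.

Everything is generated programmatically with fixed seeds; the
session-scoped fixtures exist because mesh construction and geodesic
work dominate test runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from mdsurf import (
    SurfaceMesh,
    default_ground_truth,
    extract_borders,
    make_mesh,
    make_parcellation,
    simulate_cohort,
)


def strip_mesh(n: int, spacing: float = 1.0) -> SurfaceMesh:
    """A 2 x n vertex strip in the plane: vertices 0..n-1 on the bottom row,
    n..2n-1 on top, squares split by one diagonal each."""
    xs = np.arange(n) * spacing
    verts = np.zeros((2 * n, 3))
    verts[:n, 0] = xs
    verts[n:, 0] = xs
    verts[n:, 1] = spacing
    tris = []
    for i in range(n - 1):
        tris.append((i, i + 1, n + i))
        tris.append((i + 1, n + i + 1, n + i))
    return SurfaceMesh(vertex_coords=verts, triangles=np.asarray(tris))


def grid_mesh(n: int, spacing: float = 1.0) -> SurfaceMesh:
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    verts = np.column_stack(
        [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(n * n)]
    )
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            v00 = i * n + j
            tris.append((v00, v00 + n, v00 + n + 1))
            tris.append((v00, v00 + n + 1, v00 + 1))
    return SurfaceMesh(vertex_coords=verts, triangles=np.asarray(tris))


@pytest.fixture(scope="session")
def sphere_mesh():
    """One-hemisphere icosphere, 162 vertices."""
    return make_mesh("icosphere", 2, two_hemispheres=False)


@pytest.fixture(scope="session")
def bihemi_mesh():
    """Two-hemisphere icosphere pair, 324 vertices with homolog map."""
    return make_mesh("icosphere", 2, two_hemispheres=True)


@pytest.fixture(scope="session")
def bihemi_parc(bihemi_mesh):
    return make_parcellation(bihemi_mesh, n_areas=8, seed=1)


@pytest.fixture(scope="session")
def bihemi_borders(bihemi_mesh, bihemi_parc):
    return extract_borders(bihemi_mesh, bihemi_parc)


@pytest.fixture(scope="session")
def default_truth(bihemi_mesh, bihemi_parc, bihemi_borders):
    return default_ground_truth(bihemi_mesh, bihemi_parc, bihemi_borders, seed=2)


@pytest.fixture(scope="session")
def default_cohort(bihemi_mesh, bihemi_parc, bihemi_borders, default_truth):
    return simulate_cohort(
        bihemi_mesh,
        bihemi_parc,
        default_truth,
        n_subjects=20,
        seed=3,
        borders=bihemi_borders,
    )
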