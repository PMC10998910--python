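"""Shared fixtures: canonical meshes and a session-scoped synthetic population."""

import numpy as np
import pytest
import trimesh

from spinemorph.mesh import TriMesh
from spinemorph.synthetic import FIVE_REGIMES, make_population


@pytest.fixture
def unit_cube() -> TriMesh:
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture
def regular_tetrahedron() -> TriMesh:
    # edge length 1
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    v /= np.linalg.norm(v[0] - v[1])
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriMesh(v, f)


@pytest.fixture
def icosphere_factory():
    def make(radius: float = 1.0, subdivisions: int = 3) -> TriMesh:
        ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    return make


@pytest.fixture
def open_cylinder() -> TriMesh:
    """Open-ended tube along z; bottom boundary ring centered at the origin."""
    m, n_rings = 16, 6
    theta = np.linspace(0, 2 * np.pi, m, endpoint=False)
    rings = [np.column_stack([np.cos(theta), np.sin(theta), np.full(m, z)])
             for z in np.linspace(0, 2, n_rings)]
    verts = np.vstack(rings + [[[0, 0, 2.5]]])
    faces = []
    for i in range(n_rings - 1):
        a, b = i * m, (i + 1) * m
        for j in range(m):
            jn = (j + 1) % m
            faces.append([a + j, a + jn, b + j])
            faces.append([b + j, a + jn, b + jn])
    top = (n_rings - 1) * m
    apex = len(verts) - 1
    for j in range(m):
        faces.append([top + j, top + (j + 1) % m, apex])
    return TriMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def five_regime_population():
    """1000-spine five-regime population (the clustering-recovery testbed)."""
    return make_population(n_per_family=200, families=FIVE_REGIMES, seed=12345)


@pytest.fixture(scope="session")
def five_regime_features(five_regime_population):
    return five_regime_population.features_table()
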