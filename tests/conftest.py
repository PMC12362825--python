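import numpy as np
import pytest
import trimesh as _trimesh

from genoface.mesh import TriMesh


@pytest.fixture(scope="session")
def icosphere_642() -> TriMesh:
    ico = _trimesh.creation.icosphere(subdivisions=3, radius=80.0)
    return TriMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def tetrahedron() -> TriMesh:
    """Canonical tetrahedron with consistent outward winding."""
    verts = np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                      [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
    faces = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]])
    return TriMesh(verts, faces)


@pytest.fixture(scope="session")
def grid_mesh() -> TriMesh:
    """Triangulated 7x7 regular grid (interior vertices are 6-regular)."""
    n = 7
    verts = np.array([[i, j, 0.0] for i in range(n) for j in range(n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriMesh(verts, np.array(faces))


def random_planar_mesh(rng: np.random.Generator, n_points: int) -> TriMesh:
    """Random Delaunay triangulation, used as an adversarial ring oracle."""
    from scipy.spatial import Delaunay
    pts = rng.random((n_points, 2))
    tri = Delaunay(pts)
    verts = np.column_stack([pts, np.zeros(len(pts))])
    return TriMesh(verts, tri.simplices.astype(np.int64))
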