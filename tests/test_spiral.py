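"""Ring decomposition and spiral-sequence construction."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from genoface.spiral import build_spirals, ring_structure, spiral_order
from tests.conftest import random_planar_mesh


def rings_by_edge_distance(mesh, v, k_max):
    """Independent oracle: group vertices by graph shortest-path distance."""
    V = mesh.n_vertices
    rows, cols = [], []
    for a, b, c in mesh.faces:
        for u, w in ((a, b), (b, c), (c, a)):
            rows += [u, w]
            cols += [w, u]
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(V, V))
    dist = shortest_path(g, unweighted=True, indices=v)
    return [set(np.flatnonzero(dist == k)) for k in range(k_max + 1)]


def test_tetrahedron_one_ring_is_everything_else(tetrahedron):
    rings = ring_structure(tetrahedron, 0, 1)
    assert rings[0] == {0}
    assert rings[1] == {1, 2, 3}


def test_grid_interior_two_ring_has_twelve_vertices(grid_mesh):
    center = 3 * 7 + 3
    rings = ring_structure(grid_mesh, center, 2)
    assert len(rings[1]) == 6
    assert len(rings[2]) == 12
    assert rings == rings_by_edge_distance(grid_mesh, center, 2)


def test_rings_match_bfs_oracle_on_random_meshes():
    rng = np.random.default_rng(42)
    for _ in range(20):
        mesh = random_planar_mesh(rng, int(rng.integers(10, 30)))
        v = int(rng.integers(mesh.n_vertices))
        assert ring_structure(mesh, v, 3) == rings_by_edge_distance(mesh, v, 3)


def test_rings_are_disjoint_and_union_is_disk(icosphere_642):
    rings = ring_structure(icosphere_642, 17, 4)
    seen = set()
    for r in rings:
        assert not (r & seen)
        seen |= r
    # the 4-disk is the union of rings 0..4 by construction of the oracle
    oracle = rings_by_edge_distance(icosphere_642, 17, 4)
    assert seen == set().union(*oracle)


def test_isolated_vertex_has_empty_higher_rings():
    from genoface.mesh import TriMesh
    mesh = TriMesh(np.zeros((4, 3)), np.array([[0, 1, 2]]))  # vertex 3 isolated
    rings = ring_structure(mesh, 3, 2)
    assert rings == [{3}, set(), set()]


def test_spiral_length_one_is_identity(icosphere_642):
    tab = build_spirals(icosphere_642, 1)
    assert np.array_equal(tab.sequences[:, 0], np.arange(icosphere_642.n_vertices))


def test_tetrahedron_spiral_follows_winding_convention(tetrahedron):
    # around vertex 0 the winding maps 1 -> 2 -> 3; lowest-index start is 1
    tab = build_spirals(tetrahedron, 4)
    assert list(tab.sequences[0]) == [0, 1, 2, 3]


def test_dilated_spiral_subsamples_dense_spiral(grid_mesh):
    center = 3 * 7 + 3
    dense = spiral_order(grid_mesh, center, 6)
    tab = build_spirals(grid_mesh, 3, dilation=2)
    assert list(tab.sequences[center]) == dense[::2][:3]


def test_spiral_rows_start_with_center_and_have_no_duplicates(icosphere_642):
    tab = build_spirals(icosphere_642, 9)
    V = icosphere_642.n_vertices
    assert np.array_equal(tab.sequences[:, 0], np.arange(V))
    for row in tab.sequences:
        real = row[row != tab.pad_index]
        assert len(set(real)) == len(real)


def test_spiral_entries_lie_within_the_enumerated_disk(icosphere_642):
    tab = build_spirals(icosphere_642, 9)
    for v in (0, 100, 641):
        rings = ring_structure(icosphere_642, v, 3)
        disk = set().union(*rings)
        row = tab.sequences[v]
        assert set(row[row != tab.pad_index]) <= disk


def test_spiral_deterministic_across_runs(icosphere_642):
    a = build_spirals(icosphere_642, 9).sequences
    b = build_spirals(icosphere_642, 9).sequences
    assert np.array_equal(a, b)


def test_short_disk_is_padded():
    from genoface.mesh import TriMesh
    tri = TriMesh(np.eye(3), np.array([[0, 1, 2]]))
    tab = build_spirals(tri, 5)
    assert tab.pad_index == 3
    row = tab.sequences[0]
    assert row[0] == 0 and (row == 3).sum() == 2  # only 3 reachable vertices


@pytest.mark.parametrize("bad", [dict(length=0), dict(length=3, dilation=0)])
def test_invalid_spiral_parameters_rejected(icosphere_642, bad):
    with pytest.raises(ValueError):
        build_spirals(icosphere_642, bad.get("length", 3), bad.get("dilation", 1))
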