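"""Mesh pooling hierarchies via quadric-error-metric decimation.

The mesh autoencoder pools vertex features through a fixed multiresolution
hierarchy: each level is a decimated version of the previous one, with a
sparse down-sampling map (restriction to the kept vertices) and a sparse
up-sampling map (barycentric interpolation of removed vertices from their
nearest coarse triangle).  Because each coarse vertex is a retained fine
vertex, pooling after unpooling reproduces any coarse field exactly.

Decimation is half-edge collapse ordered by the quadric error metric
(Garland-Heckbert plane quadrics), the standard choice for fixed-topology
mesh autoencoders.
"""

from __future__ import annotations

import hashlib
import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .mesh import TriMesh

__all__ = ["MeshHierarchy", "HierarchyTooDeepError", "qem_decimate", "build_hierarchy",
           "load_or_build_hierarchy"]

MIN_VERTICES = 4


class HierarchyTooDeepError(ValueError):
    """Requested pooling would reduce the mesh below the minimum size."""


@dataclass
class MeshHierarchy:
    """Fine-to-coarse mesh levels with sparse pooling/unpooling maps.

    ``down_maps[i]``: (V_{i+1}, V_i) restriction from level i to i+1.
    ``up_maps[i]``:   (V_i, V_{i+1}) barycentric prolongation back to level i;
    every row is a convex combination (nonnegative, sums to 1).
    """

    levels: list[TriMesh]
    down_maps: list[sp.csr_matrix]
    up_maps: list[sp.csr_matrix]

    @property
    def vertex_counts(self) -> list[int]:
        return [m.n_vertices for m in self.levels]


# --------------------------------------------------------------------------
# quadric-error-metric half-edge collapse
# --------------------------------------------------------------------------

def _face_quadric(v0, v1, v2) -> np.ndarray:
    n = np.cross(v1 - v0, v2 - v0)
    area = np.linalg.norm(n) / 2.0
    if area < 1e-15:
        return np.zeros((4, 4))
    n = n / (2.0 * area)
    d = -float(n @ v0)
    p = np.append(n, d)
    return area * np.outer(p, p)


def qem_decimate(mesh: TriMesh, target_v: int) -> tuple[TriMesh, np.ndarray]:
    """Collapse edges until ``target_v`` vertices remain.

    Returns the coarse mesh and ``kept``: for each coarse vertex, its index
    in the fine mesh (coarse vertex positions are a subset of fine ones).
    Each collapse moves a vertex ``u`` onto a neighbour ``v`` (half-edge
    collapse) choosing the pair with the lowest quadric error Q_u+Q_v
    evaluated at ``v``; collapses that would flip a face normal or create a
    duplicate face are rejected.
    """
    V = mesh.n_vertices
    if target_v < MIN_VERTICES:
        raise HierarchyTooDeepError(
            f"target of {target_v} vertices is below the minimum of {MIN_VERTICES}")
    verts = mesh.vertices
    quadrics = np.zeros((V, 4, 4))
    faces: set[tuple[int, int, int]] = set()
    vertex_faces: list[set[tuple[int, int, int]]] = [set() for _ in range(V)]
    for f in mesh.faces:
        key = tuple(int(x) for x in f)
        faces.add(key)
        q = _face_quadric(verts[f[0]], verts[f[1]], verts[f[2]])
        for vi in key:
            quadrics[vi] += q
            vertex_faces[vi].add(key)

    adj = mesh.vertex_adjacency()
    alive = np.ones(V, dtype=bool)
    version = np.zeros(V, dtype=np.int64)

    def edge_cost(u: int, v: int) -> float:
        p = np.append(verts[v], 1.0)
        return float(p @ (quadrics[u] + quadrics[v]) @ p)

    heap: list[tuple[float, int, int, int, int]] = []
    for u in range(V):
        for v in adj[u]:
            heapq.heappush(heap, (edge_cost(u, v), u, v, 0, 0))

    def replace_faces(u: int, v: int) -> list[tuple[tuple, tuple]] | None:
        """Plan face rewiring for collapsing u onto v; None if invalid."""
        plan = []
        for f in vertex_faces[u]:
            if v in f:
                plan.append((f, None))  # face spanned by edge (u,v): removed
                continue
            nf = tuple(v if x == u else x for x in f)
            if len(set(nf)) != 3 or nf in faces:
                return None
            # reject normal flips to keep orientation consistent
            old_n = np.cross(verts[f[1]] - verts[f[0]], verts[f[2]] - verts[f[0]])
            pts = [verts[v] if x == u else verts[x] for x in f]
            new_n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            if old_n @ new_n <= 0:
                return None
            plan.append((f, nf))
        return plan

    n_alive = V
    while n_alive > target_v and heap:
        cost, u, v, ver_u, ver_v = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or version[u] != ver_u or version[v] != ver_v:
            continue
        if v not in adj[u]:
            continue
        plan = replace_faces(u, v)
        if plan is None:
            continue
        # apply
        for f, nf in plan:
            for vi in f:
                vertex_faces[vi].discard(f)
            faces.discard(f)
            if nf is not None:
                faces.add(nf)
                for vi in nf:
                    vertex_faces[vi].add(nf)
        alive[u] = False
        n_alive -= 1
        quadrics[v] += quadrics[u]
        for w in adj[u]:
            adj[w].discard(u)
            if w != v:
                adj[v].add(w)
                adj[w].add(v)
        adj[u].clear()
        version[v] += 1
        for w in list(adj[v]):
            version[w] += 1
            heapq.heappush(heap, (edge_cost(v, w), v, w, version[v], version[w]))
            heapq.heappush(heap, (edge_cost(w, v), w, v, version[w], version[v]))

    if n_alive > target_v:
        raise RuntimeError(
            f"decimation stalled at {n_alive} vertices (target {target_v}); "
            "mesh may be too constrained")

    kept = np.flatnonzero(alive)
    remap = {int(old): new for new, old in enumerate(kept)}
    new_faces = np.array(sorted(tuple(remap[x] for x in f) for f in faces), dtype=np.int64)
    coarse = TriMesh(verts[kept], new_faces)
    return coarse, kept


def _closest_point_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                            c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point on triangle (a, b, c) to p, with barycentric weights."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3)
        return a + t * ab, np.array([1 - t, t, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6)
        return a + t * ac, np.array([1 - t, 0.0, t])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + t * (c - b), np.array([0.0, 1 - t, t])
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return a + ab * v + ac * w, np.array([1 - v - w, v, w])


def _project_to_surface(points: np.ndarray, mesh: TriMesh, n_candidates: int = 12
                        ) -> tuple[np.ndarray, np.ndarray]:
    """For each point: (triangle index, barycentric weights) of its closest
    surface point, searching triangles whose centroids are nearest."""
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    tree = cKDTree(centroids)
    k = min(n_candidates, len(centroids))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    tri_id = np.zeros(len(points), dtype=np.int64)
    bary = np.zeros((len(points), 3))
    for i, p in enumerate(points):
        best_d, best_t, best_b = np.inf, -1, None
        for t in cand[i]:
            q, b = _closest_point_triangle(p, tri[t, 0], tri[t, 1], tri[t, 2])
            d = float(np.sum((q - p) ** 2))
            if d < best_d:
                best_d, best_t, best_b = d, t, b
        tri_id[i] = best_t
        bary[i] = best_b
    return tri_id, bary


# --------------------------------------------------------------------------
# hierarchy with pooling maps
# --------------------------------------------------------------------------

def _transition_maps(fine: TriMesh, coarse: TriMesh, kept: np.ndarray
                     ) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    Vf, Vc = fine.n_vertices, coarse.n_vertices
    down = sp.csr_matrix(
        (np.ones(Vc), (np.arange(Vc), kept)), shape=(Vc, Vf))

    rows, cols, vals = [], [], []
    coarse_of_fine = np.full(Vf, -1, dtype=np.int64)
    coarse_of_fine[kept] = np.arange(Vc)
    removed = np.flatnonzero(coarse_of_fine < 0)
    for i in kept:
        rows.append(i)
        cols.append(coarse_of_fine[i])
        vals.append(1.0)
    if removed.size:
        tri_id, bary = _project_to_surface(fine.vertices[removed], coarse)
        bary = np.clip(bary, 0.0, None)
        bary /= bary.sum(axis=1, keepdims=True)
        for r, (fi, t) in enumerate(zip(removed, tri_id)):
            for corner in range(3):
                rows.append(fi)
                cols.append(coarse.faces[t, corner])
                vals.append(float(bary[r, corner]))
    up = sp.csr_matrix((vals, (rows, cols)), shape=(Vf, Vc))
    return down, up


def build_hierarchy(mesh: TriMesh, factors: list[int]) -> MeshHierarchy:
    """Decimate ``mesh`` by each factor in turn, recording pooling maps.

    ``factors = [4, 4, 4, 4]`` yields five levels whose vertex counts
    shrink by roughly 4 at each transition (exact targets are
    ``round(V / factor)``).
    """
    if not factors:
        raise ValueError("factors must be nonempty")
    levels = [mesh]
    down_maps, up_maps = [], []
    for f in factors:
        fine = levels[-1]
        target = int(round(fine.n_vertices / f))
        if target < MIN_VERTICES:
            raise HierarchyTooDeepError(
                f"pooling by {f} from {fine.n_vertices} vertices would leave "
                f"{target} < {MIN_VERTICES}")
        coarse, kept = qem_decimate(fine, target)
        down, up = _transition_maps(fine, coarse, kept)
        levels.append(coarse)
        down_maps.append(down)
        up_maps.append(up)
    return MeshHierarchy(levels=levels, down_maps=down_maps, up_maps=up_maps)


# --------------------------------------------------------------------------
# HDF5 sidecar cache
# --------------------------------------------------------------------------

def mesh_hash(mesh: TriMesh) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(mesh.vertices).tobytes())
    h.update(np.ascontiguousarray(mesh.faces).tobytes())
    return h.hexdigest()


def load_or_build_hierarchy(mesh: TriMesh, factors: list[int],
                            cache_path=None) -> MeshHierarchy:
    """Build a hierarchy, caching it in an HDF5 sidecar keyed by mesh hash."""
    if cache_path is None:
        return build_hierarchy(mesh, factors)
    import h5py

    key = f"{mesh_hash(mesh)}-{'x'.join(map(str, factors))}"
    try:
        with h5py.File(cache_path, "r") as fh:
            if key in fh:
                grp = fh[key]
                n = int(grp.attrs["n_levels"])
                levels = [TriMesh(grp[f"v{i}"][()], grp[f"f{i}"][()]) for i in range(n)]
                down_maps, up_maps = [], []
                for i in range(n - 1):
                    down_maps.append(_read_csr(grp, f"down{i}"))
                    up_maps.append(_read_csr(grp, f"up{i}"))
                return MeshHierarchy(levels, down_maps, up_maps)
    except OSError:
        pass
    hier = build_hierarchy(mesh, factors)
    with h5py.File(cache_path, "a") as fh:
        grp = fh.create_group(key)
        grp.attrs["n_levels"] = len(hier.levels)
        for i, lvl in enumerate(hier.levels):
            grp.create_dataset(f"v{i}", data=lvl.vertices)
            grp.create_dataset(f"f{i}", data=lvl.faces)
        for i, (d, u) in enumerate(zip(hier.down_maps, hier.up_maps)):
            _write_csr(grp, f"down{i}", d)
            _write_csr(grp, f"up{i}", u)
    return hier


def _write_csr(grp, name: str, mat: sp.csr_matrix):
    g = grp.create_group(name)
    g.create_dataset("data", data=mat.data)
    g.create_dataset("indices", data=mat.indices)
    g.create_dataset("indptr", data=mat.indptr)
    g.attrs["shape"] = mat.shape


def _read_csr(grp, name: str) -> sp.csr_matrix:
    g = grp[name]
    return sp.csr_matrix(
        (g["data"][()], g["indices"][()], g["indptr"][()]),
        shape=tuple(g.attrs["shape"]))
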