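"""Ring decompositions and spiral sequences on triangle meshes.

A spiral sequence enumerates the neighbourhood of a vertex ``v`` as an
ordered list: the 0-ring is ``{v}`` itself, the (k+1)-ring is the set of
neighbours of the k-ring not already inside the k-disk (the union of
rings 0..k), and the spiral concatenates rings in order, each ring laid
out counter-clockwise with respect to the mesh's face winding.  Spiral
convolutions gather vertex features along these fixed sequences, which is
what lets an MLP act like a convolution kernel on an irregular mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh

__all__ = ["SpiralTable", "ring_structure", "spiral_order", "build_spirals"]


@dataclass
class SpiralTable:
    """Per-vertex spiral sequences of fixed length.

    ``sequences[v, 0] == v``; truncated spirals (vertices whose reachable
    disk is too small) are padded with ``pad_index`` (= V, a virtual vertex
    whose features read as zeros).
    """

    sequences: np.ndarray  # (V, length) int
    length: int
    dilation: int
    pad_index: int


def ring_structure(mesh: TriMesh, v: int, k_max: int) -> list[set[int]]:
    """Return [0-ring, 1-ring, ..., k_max-ring] around vertex ``v``.

    Defined by the recurrence ring_{k+1} = N(ring_k) \\ disk_k, which equals
    grouping vertices by edge distance from ``v``.  Rings beyond the
    connected component of ``v`` are empty sets.
    """
    if not (0 <= v < mesh.n_vertices):
        raise IndexError(f"vertex {v} out of range")
    adj = mesh.vertex_adjacency()
    disk = {v}
    rings = [{v}]
    for _ in range(k_max):
        frontier: set[int] = set()
        for u in rings[-1]:
            frontier |= adj[u]
        ring = frontier - disk
        rings.append(ring)
        disk |= ring
    return rings


def _ordered_one_ring(mesh_nxt: list[dict[int, int]], adj: list[set[int]], v: int) -> list[int]:
    """One-ring of ``v`` in CCW order, starting at its lowest-index neighbour.

    On a closed manifold the winding map is a single cycle; at boundaries
    the walk may stop early, and any unreached neighbours are appended in
    index order (open-star convention, no mirroring).
    """
    neighbours = adj[v]
    if not neighbours:
        return []
    start = min(neighbours)
    order = [start]
    seen = {start}
    cur = start
    while True:
        nxt = mesh_nxt[v].get(cur)
        if nxt is None or nxt in seen:
            break
        order.append(nxt)
        seen.add(nxt)
        cur = nxt
    for u in sorted(neighbours - seen):
        order.append(u)
    return order


def spiral_order(mesh: TriMesh, v: int, n: int,
                 _cache: dict | None = None) -> list[int]:
    """First ``n`` vertices of the spiral around ``v`` (ring-by-ring, CCW).

    Ring k+1 is ordered by walking ring k in its stored order and, for each
    of its vertices, appending that vertex's CCW-ordered neighbours that
    belong to ring k+1 and were not appended yet.  This starts ring k+1 at
    a vertex adjacent to ring k's first element and follows the winding
    orientation, so the enumeration is deterministic for a given mesh.
    """
    if _cache is None:
        _cache = {}
    nxt = _cache.setdefault("nxt", mesh.winding_next())
    adj = _cache.setdefault("adj", mesh.vertex_adjacency())

    spiral = [v]
    disk = {v}
    ring = _ordered_one_ring(nxt, adj, v)
    while ring and len(spiral) < n:
        spiral.extend(ring)
        disk.update(ring)
        nxt_ring: list[int] = []
        nxt_set: set[int] = set()
        for u in ring:
            for w in _ordered_one_ring(nxt, adj, u):
                if w not in disk and w not in nxt_set:
                    nxt_ring.append(w)
                    nxt_set.add(w)
        ring = nxt_ring
    return spiral[:n]


def build_spirals(mesh: TriMesh, length: int, dilation: int = 1) -> SpiralTable:
    """Build the (V, length) spiral table with the given dilation.

    A dilated spiral enumerates the full spiral of ``length * dilation``
    vertices and keeps every ``dilation``-th element (positions 0, d, 2d,
    ...), widening the receptive field at constant cost.  Rows start with
    the centre vertex; short spirals are padded with ``pad_index = V``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    V = mesh.n_vertices
    pad = V
    table = np.full((V, length), pad, dtype=np.int64)
    cache: dict = {}
    n_full = length * dilation
    for v in range(V):
        sp = spiral_order(mesh, v, n_full, _cache=cache)
        sp = sp[::dilation][:length]
        table[v, : len(sp)] = sp
    return SpiralTable(sequences=table, length=length, dilation=dilation, pad_index=pad)
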