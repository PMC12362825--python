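"""Triangle-mesh container and PLY/OBJ I/O.

Meshes in this package are registered point clouds: every mesh in a
dataset shares one fixed triangulation, so vertex ``i`` is the same
anatomical location on every face.  Coordinates are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = ["TriMesh", "MeshFormatError", "read_mesh", "write_mesh"]


class MeshFormatError(ValueError):
    """Raised for malformed or unsupported mesh files."""


@dataclass
class TriMesh:
    """Vertices (V, 3) in mm and triangle faces (F, 3) of 0-based indices."""

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError(f"faces must be triangles (F, 3), got {self.faces.shape}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), dict(self.metadata))

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        return TriMesh(np.asarray(vertices), self.faces, dict(self.metadata))

    # ---- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``MeshFormatError`` if broken.

        Invariants: all indices in range, no degenerate (repeated-index)
        faces, every edge borders at most two faces, and winding is
        consistent (each shared edge is traversed once per direction).
        """
        V, F = self.n_vertices, self.faces
        if F.size and (F.min() < 0 or F.max() >= V):
            raise MeshFormatError("face index out of range")
        if any(len(set(f)) != 3 for f in F):
            raise MeshFormatError("degenerate face with repeated vertex index")
        directed: dict[tuple[int, int], int] = {}
        for f in F:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                directed[(a, b)] = directed.get((a, b), 0) + 1
        for (a, b), c in directed.items():
            if c > 1:
                raise MeshFormatError(f"inconsistent winding: directed edge {(a, b)} used {c} times")
            if c + directed.get((b, a), 0) > 2:
                raise MeshFormatError(f"edge {(a, b)} borders more than two faces")

    # ---- adjacency helpers ----------------------------------------------
    def vertex_adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.faces:
            adj[a].update((b, c))
            adj[b].update((a, c))
            adj[c].update((a, b))
        return adj

    def winding_next(self) -> list[dict[int, int]]:
        """Per-vertex CCW rotation maps from consistent face winding.

        For face (v, a, b), ``nxt[v][a] = b``: walking ``nxt[v]`` enumerates
        the one-ring of ``v`` counter-clockwise w.r.t. the face orientation.
        """
        nxt: list[dict[int, int]] = [{} for _ in range(self.n_vertices)]
        for f in self.faces:
            for i in range(3):
                v, a, b = f[i], f[(i + 1) % 3], f[(i + 2) % 3]
                nxt[v][a] = b
        return nxt

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _read_obj(path: Path) -> TriMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tag, *rest = line.split()
            if tag == "v":
                if len(rest) < 3:
                    raise MeshFormatError(f"{path}:{lineno}: vertex line needs 3 coordinates: {line!r}")
                try:
                    vertices.append([float(x) for x in rest[:3]])
                except ValueError as e:
                    raise MeshFormatError(f"{path}:{lineno}: bad vertex coordinate: {line!r}") from e
            elif tag == "f":
                if len(rest) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: only triangular faces are supported, got {len(rest)} vertices"
                    )
                idx = []
                for tok in rest:
                    try:
                        idx.append(int(tok.split("/")[0]) - 1)
                    except ValueError as e:
                        raise MeshFormatError(f"{path}:{lineno}: bad face index: {line!r}") from e
                faces.append(idx)
            # other OBJ directives (vn, vt, o, g, s, usemtl ...) are ignored
    if not vertices:
        raise MeshFormatError(f"{path}: no vertices found")
    return TriMesh(np.array(vertices), np.array(faces).reshape(-1, 3))


def read_mesh(path: str | Path) -> TriMesh:
    """Read a PLY (ascii or binary) or OBJ mesh; faces must be triangles."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        return _read_obj(path)
    if suffix == ".ply":
        try:
            tm = _trimesh.load(path, file_type="ply", process=False)
        except Exception as e:
            raise MeshFormatError(f"{path}: failed to parse PLY: {e}") from e
        faces = np.asarray(tm.faces)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshFormatError(f"{path}: only triangular faces are supported")
        return TriMesh(np.asarray(tm.vertices), faces)
    raise MeshFormatError(f"{path}: unsupported mesh format {suffix!r} (use .ply or .obj)")


def write_mesh(mesh: TriMesh, path: str | Path, encoding: str = "binary") -> None:
    """Write ``mesh`` as PLY (``encoding`` = 'binary' or 'ascii') or OBJ.

    Round-tripping preserves connectivity exactly and coordinates to well
    below 1e-6 (PLY stores float32; OBJ is written with 9 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    elif suffix == ".ply":
        _write_ply(mesh, path, encoding)
    else:
        raise MeshFormatError(f"{path}: unsupported mesh format {suffix!r} (use .ply or .obj)")


def _write_ply(mesh: TriMesh, path: Path, encoding: str) -> None:
    """PLY writer with double-precision vertices (ascii or binary LE)."""
    if encoding not in ("ascii", "binary"):
        raise ValueError(f"encoding must be 'ascii' or 'binary', got {encoding!r}")
    fmt = "ascii 1.0" if encoding == "ascii" else "binary_little_endian 1.0"
    header = (
        f"ply\nformat {fmt}\ncomment genoface\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if encoding == "ascii":
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))
        else:
            fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
            counts = np.full((mesh.n_faces, 1), 3, dtype=np.uint8)
            idx = np.ascontiguousarray(mesh.faces, dtype="<i4")
            rec = np.zeros(mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = counts[:, 0]
            rec["idx"] = idx
            fh.write(rec.tobytes())
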