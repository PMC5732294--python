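"""Triangle surface meshes: container, icosphere generator, OFF/PLY I/O.

Meshes are the source of the graph's *local* edges: every undirected pair of
vertices sharing a triangle edge becomes a local connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InputError

MAX_ICOSPHERE_ORDER = 6


@dataclass
class SurfaceMesh:
    """Closed or open triangle mesh with optional per-vertex hemisphere tags.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (f, 3) int array
        Vertex-index triples.
    hemisphere : (n,) array of str, optional
        ``"L"`` / ``"R"`` tag per vertex.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError("vertices must be an (n, 3) array")
        if self.n_vertices == 0:
            raise InputError("mesh has no vertices")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_vertices
        ):
            raise InputError("triangle indices out of range")
        tri = self.triangles
        if tri.size:
            degenerate = (
                (tri[:, 0] == tri[:, 1])
                | (tri[:, 1] == tri[:, 2])
                | (tri[:, 0] == tri[:, 2])
            )
            if degenerate.any():
                raise InputError(
                    f"{int(degenerate.sum())} degenerate triangle(s) with a repeated index"
                )
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if self.hemisphere.shape != (self.n_vertices,):
                raise InputError("hemisphere must have one tag per vertex")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges (i < j) appearing in at least one triangle."""
        tri = self.triangles
        if tri.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        pairs = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        pairs = np.sort(pairs, axis=1)
        return np.unique(pairs, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_triangles


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def make_icosphere(subdivision_order: int, *, radius: float = 1.0) -> SurfaceMesh:
    """Recursively subdivided icosahedron projected to a sphere.

    Vertex count is ``10 * 4**order + 2``; order 5 gives 10,242 vertices.
    """
    if subdivision_order < 0:
        raise InputError("subdivision order must be non-negative")
    if subdivision_order > MAX_ICOSPHERE_ORDER:
        raise InputError(
            f"subdivision order {subdivision_order} exceeds maximum {MAX_ICOSPHERE_ORDER}"
        )
    verts, faces = _icosahedron()
    verts = list(verts)
    for _ in range(subdivision_order):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint.get(key)
            if idx is None:
                p = verts[i] + verts[j]
                p /= np.linalg.norm(p)
                verts.append(p)
                idx = len(verts) - 1
                midpoint[key] = idx
            return idx

        new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
        for f, (a, b, c) in enumerate(faces):
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces[4 * f : 4 * f + 4] = [
                [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
            ]
        faces = new_faces
    vertices = np.asarray(verts) * radius
    return SurfaceMesh(vertices=vertices, triangles=faces)


# ---------------------------------------------------------------------------
# ASCII mesh I/O


def write_off(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_off(path) -> SurfaceMesh:
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    try:
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            cnt = int(tokens[pos])
            if cnt != 3:
                raise FormatError(f"{path}: only triangle faces supported")
            faces.append([int(t) for t in tokens[pos + 1 : pos + 4]])
            pos += 1 + cnt
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: truncated or malformed OFF file") from exc
    return SurfaceMesh(vertices=verts, triangles=np.asarray(faces, dtype=np.int64))


def write_ply(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path) -> SurfaceMesh:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: missing ply header")
    nv = nf = None
    body_at = None
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split()
        if parts[:2] == ["element", "vertex"]:
            nv = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            nf = int(parts[2])
        elif parts[:1] == ["end_header"]:
            body_at = i + 1
            break
        elif parts[:2] == ["format", "binary_little_endian"] or parts[:2] == [
            "format",
            "binary_big_endian",
        ]:
            raise FormatError(f"{path}: binary PLY not supported")
    if nv is None or nf is None or body_at is None:
        raise FormatError(f"{path}: incomplete PLY header")
    try:
        verts = np.array(
            [lines[body_at + i].split()[:3] for i in range(nv)], dtype=float
        )
        faces = []
        for i in range(nf):
            parts = lines[body_at + nv + i].split()
            if int(parts[0]) != 3:
                raise FormatError(f"{path}: only triangle faces supported")
            faces.append([int(p) for p in parts[1:4]])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: truncated or malformed PLY file") from exc
    return SurfaceMesh(vertices=verts, triangles=np.asarray(faces, dtype=np.int64))


def read_mesh(path) -> SurfaceMesh:
    """Dispatch on file extension (.off / .ply)."""
    p = str(path).lower()
    if p.endswith(".off"):
        return read_off(path)
    if p.endswith(".ply"):
        return read_ply(path)
    raise FormatError(f"unrecognized mesh format: {path}")
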