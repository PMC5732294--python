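"""Vertex-level connectome graphs.

A connectome graph combines *local* edges (shared triangle edges of a cortical
surface mesh) with *long-range* edges (fiber endpoint pairs, supplied as vertex
index pairs or synthesized). Single-subject graphs are binary and undirected;
group averages carry fractional weights in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InputError
from .mesh import SurfaceMesh, make_icosphere

__all__ = [
    "LongRangeEdges",
    "ConnectomeGraph",
    "build_adjacency",
    "average_graphs",
    "prune_isolated",
    "synth_connectome",
    "save_graph",
    "load_graph",
    "read_long_edges",
    "write_long_edges",
]


@dataclass
class LongRangeEdges:
    """Long-distance connections as endpoint vertex-index pairs."""

    pairs: np.ndarray
    provenance: str = "tractography-import"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)

    def validate(self, n_vertices: int) -> None:
        if self.pairs.size == 0:
            return
        if self.pairs.min() < 0 or self.pairs.max() >= n_vertices:
            raise InputError("long-range edge index out of range")
        self_pairs = self.pairs[:, 0] == self.pairs[:, 1]
        if self_pairs.any():
            bad = self.pairs[self_pairs][0, 0]
            raise InputError(f"self-pair ({bad}, {bad}) is not a valid long-range edge")


@dataclass
class ConnectomeGraph:
    """Sparse symmetric connectivity with edge provenance.

    ``vertex_map`` holds the original vertex id of each retained graph index,
    so column ``j`` of any downstream basis refers to original vertex
    ``vertex_map[j]``.
    """

    adjacency: sp.csr_matrix
    local_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    long_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    vertex_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        self.adjacency.sum_duplicates()
        self.adjacency.sort_indices()
        n = self.adjacency.shape[0]
        if self.adjacency.shape[1] != n:
            raise InputError("adjacency must be square")
        if self.adjacency.diagonal().any():
            raise InputError("adjacency diagonal must be zero")
        sym_gap = abs(self.adjacency - self.adjacency.T)
        if sym_gap.nnz and sym_gap.max() > 1e-12:
            raise InputError("adjacency must be symmetric")
        if self.adjacency.nnz and self.adjacency.data.min() < 0:
            raise InputError("adjacency weights must be non-negative")
        self.local_edges = np.asarray(self.local_edges, dtype=np.int64).reshape(-1, 2)
        self.long_edges = np.asarray(self.long_edges, dtype=np.int64).reshape(-1, 2)
        if self.vertex_map is None:
            self.vertex_map = np.arange(n, dtype=np.int64)
        else:
            self.vertex_map = np.asarray(self.vertex_map, dtype=np.int64)
            if self.vertex_map.shape != (n,):
                raise InputError("vertex_map must list one original id per vertex")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def _edges_to_adjacency(n: int, edges: np.ndarray) -> sp.csr_matrix:
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    data = np.ones(2 * len(edges))
    a = sp.coo_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    a.data[:] = 1.0  # collapse duplicate entries to binary
    return a


def build_adjacency(mesh: SurfaceMesh, long_edges: LongRangeEdges) -> ConnectomeGraph:
    """Binary adjacency: mesh edges plus long-range pairs (Boolean union).

    A long pair that duplicates a mesh edge is counted once and flagged local.
    """
    n = mesh.n_vertices
    long_edges.validate(n)
    local = mesh.edges()
    local_set = {tuple(e) for e in local}
    long_pairs = np.sort(long_edges.pairs, axis=1)
    if len(long_pairs):
        long_pairs = np.unique(long_pairs, axis=0)
        novel = np.array([tuple(e) not in local_set for e in long_pairs])
        long_pairs = long_pairs[novel]
    all_edges = np.concatenate([local, long_pairs]) if len(long_pairs) else local
    return ConnectomeGraph(
        adjacency=_edges_to_adjacency(n, all_edges),
        local_edges=local,
        long_edges=long_pairs,
    )


def average_graphs(graphs: list[ConnectomeGraph]) -> ConnectomeGraph:
    """Entrywise mean adjacency across subjects; provenance masks are unioned."""
    if not graphs:
        raise InputError("no graphs to average")
    n = graphs[0].n
    for g in graphs[1:]:
        if g.n != n:
            raise InputError(f"graph sizes differ: {g.n} != {n}")
    mean = sum(g.adjacency for g in graphs) / len(graphs)
    local = np.unique(np.concatenate([g.local_edges for g in graphs]), axis=0)
    longe = np.unique(np.concatenate([g.long_edges for g in graphs]), axis=0)
    return ConnectomeGraph(
        adjacency=sp.csr_matrix(mean),
        local_edges=local,
        long_edges=longe,
        vertex_map=graphs[0].vertex_map.copy(),
    )


def prune_isolated(graph: ConnectomeGraph) -> ConnectomeGraph:
    """Drop zero-degree vertices; vertex_map records original ids of survivors."""
    deg = graph.degrees()
    keep = deg > 0
    if not keep.any():
        raise InputError("all vertices are isolated")
    if keep.all():
        return graph
    new_index = -np.ones(graph.n, dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))

    def remap(edges: np.ndarray) -> np.ndarray:
        if len(edges) == 0:
            return edges
        mapped = new_index[edges]
        return mapped[(mapped >= 0).all(axis=1)]

    sub = graph.adjacency[keep][:, keep]
    return ConnectomeGraph(
        adjacency=sub.tocsr(),
        local_edges=remap(graph.local_edges),
        long_edges=remap(graph.long_edges),
        vertex_map=graph.vertex_map[keep],
    )


def _two_hemisphere_mesh(order: int, separation: float) -> SurfaceMesh:
    left = make_icosphere(order)
    right = make_icosphere(order)
    lv = left.vertices - np.array([separation / 2.0, 0.0, 0.0])
    rv = right.vertices + np.array([separation / 2.0, 0.0, 0.0])
    nv = left.n_vertices
    return SurfaceMesh(
        vertices=np.vstack([lv, rv]),
        triangles=np.vstack([left.triangles, right.triangles + nv]),
        hemisphere=np.array(["L"] * nv + ["R"] * nv),
    )


def _sample_weighted_pairs(
    rng: np.random.Generator,
    coords: np.ndarray,
    candidates_mask,  # callable (i, j arrays) -> bool array of admissible pairs
    n_wanted: int,
    decay: float,
    forbidden: set[tuple[int, int]],
) -> np.ndarray:
    """Sample distinct vertex pairs w.p. proportional to exp(-distance/decay).

    Small graphs enumerate all pairs and draw a weighted sample without
    replacement (Gumbel top-k); large graphs fall back to rejection sampling.
    """
    n = len(coords)
    if n_wanted == 0:
        return np.empty((0, 2), dtype=np.int64)
    if n <= 2500:
        iu, ju = np.triu_indices(n, k=1)
        ok = candidates_mask(iu, ju)
        iu, ju = iu[ok], ju[ok]
        if len(forbidden):
            allowed = np.array([(a, b) not in forbidden for a, b in zip(iu, ju)])
            iu, ju = iu[allowed], ju[allowed]
        if n_wanted > len(iu):
            raise InputError(
                f"requested {n_wanted} long-range edges but only {len(iu)} pairs available"
            )
        dist = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        logw = -dist / decay
        keys = logw + rng.gumbel(size=len(iu))
        top = np.argpartition(-keys, n_wanted - 1)[:n_wanted]
        return np.stack([iu[top], ju[top]], axis=1)
    # rejection sampling: weights exp(-d/decay) <= 1
    chosen: set[tuple[int, int]] = set()
    out = []
    max_rounds = 2000
    for _ in range(max_rounds):
        if len(out) >= n_wanted:
            break
        batch = max(4 * (n_wanted - len(out)), 256)
        i = rng.integers(0, n, size=batch)
        j = rng.integers(0, n, size=batch)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        ok = (lo != hi) & candidates_mask(lo, hi)
        lo, hi = lo[ok], hi[ok]
        d = np.linalg.norm(coords[lo] - coords[hi], axis=1)
        accept = rng.random(len(lo)) < np.exp(-d / decay)
        for a, b in zip(lo[accept], hi[accept]):
            key = (int(a), int(b))
            if key in forbidden or key in chosen:
                continue
            chosen.add(key)
            out.append(key)
            if len(out) == n_wanted:
                break
    if len(out) < n_wanted:
        raise InputError(
            f"could not place {n_wanted} long-range edges "
            f"(only {len(out)} accepted; decay {decay} may be too small)"
        )
    return np.asarray(out, dtype=np.int64)


def synth_connectome(
    order: int,
    n_long_edges: int,
    distance_decay: float,
    seed: int,
    *,
    inter_hemisphere_fraction: float = 0.25,
    separation: float = 2.5,
) -> ConnectomeGraph:
    """Two icosphere hemispheres plus seeded distance-decayed long-range edges.

    Hemispheres occupy disjoint vertex blocks (left block first). Long-range
    pairs are drawn without replacement with probability proportional to
    ``exp(-distance / distance_decay)``; a configurable fraction is forced to
    be inter-hemispheric. Deterministic under a fixed seed.
    """
    if n_long_edges < 0:
        raise InputError("n_long_edges must be non-negative")
    if distance_decay <= 0:
        raise InputError("distance_decay must be positive")
    if not 0.0 <= inter_hemisphere_fraction <= 1.0:
        raise InputError("inter_hemisphere_fraction must lie in [0, 1]")
    mesh = _two_hemisphere_mesh(order, separation)
    rng = np.random.default_rng(seed)
    local = mesh.edges()
    forbidden = {tuple(e) for e in local}
    half = mesh.n_vertices // 2
    coords = mesh.vertices
    n_inter = int(round(inter_hemisphere_fraction * n_long_edges))
    n_intra = n_long_edges - n_inter

    def inter_mask(i, j):
        return (i < half) != (j < half)

    def intra_mask(i, j):
        return (i < half) == (j < half)

    inter = _sample_weighted_pairs(rng, coords, inter_mask, n_inter, distance_decay, forbidden)
    intra = _sample_weighted_pairs(rng, coords, intra_mask, n_intra, distance_decay, forbidden)
    long_pairs = np.concatenate([inter, intra])
    graph = build_adjacency(mesh, LongRangeEdges(long_pairs, provenance="synthetic"))
    return graph


# ---------------------------------------------------------------------------
# I/O


def save_graph(graph: ConnectomeGraph, path) -> None:
    """Write the adjacency in Matrix Market coordinate format (symmetric)."""
    scipy.io.mmwrite(str(path), graph.adjacency, symmetry="symmetric")


def load_graph(path) -> ConnectomeGraph:
    try:
        a = scipy.io.mmread(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad files
        raise FormatError(f"{path}: not a readable Matrix Market file") from exc
    return ConnectomeGraph(adjacency=sp.csr_matrix(a))


def write_long_edges(edges: LongRangeEdges, n_vertices: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_vertices={n_vertices}\n")
        for a, b in edges.pairs:
            fh.write(f"{a}\t{b}\n")


def read_long_edges(path) -> tuple[LongRangeEdges, int | None]:
    """Read a 2-column TSV of 0-based vertex index pairs.

    Returns the edges and the declared vertex count (from the
    ``# n_vertices=<n>`` header) if present.
    """
    n_vertices = None
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_vertices=" in line:
                    n_vertices = int(line.split("n_vertices=")[1].split()[0])
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: expected two columns, got {line!r}")
            pairs.append((int(parts[0]), int(parts[1])))
    edges = LongRangeEdges(np.asarray(pairs, dtype=np.int64).reshape(-1, 2))
    return edges, n_vertices
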