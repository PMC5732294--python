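"""Symmetric normalized graph Laplacian and its eigenmodes (harmonics).

The Laplacian is ``D^{-1/2} (D - A) D^{-1/2}`` with weighted degrees; its
eigenvalues lie in [0, 2], attained exactly by bipartite graphs (K2 at 2).
Eigenvectors are the harmonic basis: orthonormal spatial patterns indexed by
wavenumber k (1-based rank of the eigenvalue in ascending order).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .connectome import ConnectomeGraph
from .errors import FormatError, InputError, IntegrityError, SolverError

DENSE_SOLVE_MAX_N = 2000
RESIDUAL_TOL = 1e-6


def graph_fingerprint(adjacency: sp.spmatrix) -> str:
    """SHA-256 of the canonical CSR representation of an adjacency matrix."""
    a = sp.csr_matrix(adjacency).copy()
    a.sum_duplicates()
    a.sort_indices()
    h = hashlib.sha256()
    h.update(np.asarray(a.shape, dtype=np.int64).tobytes())
    h.update(a.indptr.astype(np.int64).tobytes())
    h.update(a.indices.astype(np.int64).tobytes())
    h.update(a.data.astype(np.float64).tobytes())
    return h.hexdigest()


def graph_laplacian(graph: ConnectomeGraph) -> sp.csr_matrix:
    """Symmetric normalized Laplacian ``D^{-1/2} (D - A) D^{-1/2}``.

    Raises a precondition error naming the first zero-degree vertex — prune
    isolates first.
    """
    deg = graph.degrees()
    zero = np.flatnonzero(deg <= 0)
    if len(zero):
        raise InputError(
            f"vertex {int(zero[0])} has zero degree; prune isolated vertices first"
        )
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    n = graph.n
    lap = sp.identity(n, format="csr") - d_inv_sqrt @ graph.adjacency @ d_inv_sqrt
    lap = (lap + lap.T) / 2.0  # kill asymmetric rounding noise
    return sp.csr_matrix(lap)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-|entry| element positive (ties: lowest index)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


@dataclass
class HarmonicBasis:
    """Orthonormal Laplacian eigenpairs, ascending eigenvalue order."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    graph_fingerprint: str
    solver: str = "dense"
    tolerance: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        if self.eigenvectors.ndim != 2:
            raise InputError("eigenvectors must be an (n, m) array")
        if self.eigenvectors.shape[1] != self.eigenvalues.shape[0]:
            raise InputError("eigenvalue / eigenvector count mismatch")

    @property
    def n(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def m(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def wavenumbers(self) -> np.ndarray:
        """1-based spectral index k."""
        return np.arange(1, self.m + 1)

    def truncated(self, m: int) -> "HarmonicBasis":
        if m > self.m:
            raise InputError(f"cannot truncate to {m} > {self.m} modes")
        return HarmonicBasis(
            eigenvalues=self.eigenvalues[:m],
            eigenvectors=self.eigenvectors[:, :m],
            graph_fingerprint=self.graph_fingerprint,
            solver=self.solver,
            tolerance=self.tolerance,
            meta=dict(self.meta),
        )


def compute_harmonics(
    laplacian: sp.spmatrix,
    m: int | str = "all",
    *,
    fingerprint: str | None = None,
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> HarmonicBasis:
    """Smallest-``m`` eigenpairs of the Laplacian, ascending and sign-fixed.

    Dense solve for n <= 2,000 or when all modes are requested at small n;
    otherwise shift-invert Lanczos around the bottom of the spectrum. Every
    returned mode satisfies ``||L psi - lambda psi|| <= 1e-6``.
    """
    lap = sp.csr_matrix(laplacian)
    n = lap.shape[0]
    if m == "all":
        m = n
    m = int(m)
    if m < 1 or m > n:
        raise InputError(f"requested {m} modes for an n={n} graph")

    if n <= DENSE_SOLVE_MAX_N or m >= n - 1:
        vals, vecs = np.linalg.eigh(lap.toarray())
        vals, vecs = vals[:m], vecs[:, :m]
        solver = "dense"
    else:
        try:
            vals, vecs = spla.eigsh(
                lap, k=m, sigma=-0.01, which="LM", tol=tol, maxiter=maxiter
            )
        except spla.ArpackNoConvergence as exc:
            raise SolverError(
                f"eigensolver did not converge: {len(exc.eigenvalues)}/{m} modes "
                f"after maxiter iterations"
            ) from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        solver = "shift-invert"

    # snap numerical noise at the spectrum boundaries
    vals = vals.copy()
    vals[np.abs(vals) < 1e-10] = 0.0
    vals[(vals > 2.0) & (vals < 2.0 + 1e-10)] = 2.0
    vecs = _fix_signs(vecs)

    residual = np.linalg.norm(lap @ vecs - vecs * vals, axis=0)
    if residual.max() > RESIDUAL_TOL:
        raise SolverError(
            f"eigen-residual {residual.max():.2e} exceeds {RESIDUAL_TOL:.0e} "
            f"(worst mode {int(residual.argmax()) + 1})"
        )
    return HarmonicBasis(
        eigenvalues=vals,
        eigenvectors=vecs,
        graph_fingerprint=fingerprint or "",
        solver=solver,
        tolerance=tol,
        meta={"n": n, "m": m},
    )


def harmonics_of(graph: ConnectomeGraph, m: int | str = "all", **kw) -> HarmonicBasis:
    """Convenience: Laplacian + eigensolve + fingerprint in one call."""
    return compute_harmonics(
        graph_laplacian(graph), m, fingerprint=graph_fingerprint(graph.adjacency), **kw
    )


# ---------------------------------------------------------------------------
# Persistence (HDF5 container + JSON provenance sidecar)


def save_basis(basis: HarmonicBasis, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("eigenvalues", data=basis.eigenvalues)
        fh.create_dataset("eigenvectors", data=basis.eigenvectors)
        fh.attrs["graph_fingerprint"] = basis.graph_fingerprint
        fh.attrs["solver"] = basis.solver
        fh.attrs["tolerance"] = basis.tolerance
    with open(str(path) + ".json", "w") as fh:
        json.dump(
            {
                "graph_fingerprint": basis.graph_fingerprint,
                "solver": basis.solver,
                "tolerance": basis.tolerance,
                "n": basis.n,
                "m": basis.m,
            },
            fh,
            indent=2,
        )


def load_basis(path, *, graph: ConnectomeGraph | None = None) -> HarmonicBasis:
    """Load a basis; if ``graph`` is given its fingerprint must match."""
    import h5py

    try:
        with h5py.File(path, "r") as fh:
            basis = HarmonicBasis(
                eigenvalues=fh["eigenvalues"][...],
                eigenvectors=fh["eigenvectors"][...],
                graph_fingerprint=str(fh.attrs["graph_fingerprint"]),
                solver=str(fh.attrs["solver"]),
                tolerance=float(fh.attrs["tolerance"]),
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"{path}: not a readable basis file") from exc
    if graph is not None:
        expect = graph_fingerprint(graph.adjacency)
        if expect != basis.graph_fingerprint:
            raise IntegrityError(
                "basis fingerprint does not match the supplied graph"
            )
    return basis
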