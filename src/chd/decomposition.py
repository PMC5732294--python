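"""Projection of vertex-mapped time series onto a harmonic basis.

``decompose`` computes alpha_k(t) = <F_t, psi_k> (plain Euclidean inner
product over vertices); power is |alpha| and energy |alpha|^2 * lambda^2.
With a full basis the decomposition satisfies Parseval's identity and
``sum_k E(k, t) = ||L F_t||^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InputError, IntegrityError
from .harmonics import HarmonicBasis

__all__ = [
    "FunctionalSeries",
    "SpectralCoefficients",
    "PowerTensor",
    "EnergyTensor",
    "decompose",
    "reconstruct",
    "power",
    "energy",
    "zscore_vertices",
    "read_functional_tsv",
    "write_functional_tsv",
]


@dataclass
class FunctionalSeries:
    """Vertex x time activity matrix plus scan metadata."""

    data: np.ndarray
    tr: float | None = None
    subject_id: str | None = None
    condition: str | None = None
    scan_order: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InputError("functional data must be a (vertices, time) matrix")
        if not np.isfinite(self.data).all():
            raise InputError("functional data contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SpectralCoefficients:
    """Harmonic x time coefficient matrix alpha_k(t)."""

    alpha: np.ndarray
    basis_fingerprint: str = ""
    preprocessing: str = "raw"
    subject_id: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if self.alpha.ndim != 2:
            raise InputError("alpha must be an (m, T) matrix")

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.alpha.shape[1]


@dataclass
class PowerTensor:
    """P(psi_k, t) = |alpha_k(t)|, with per-harmonic and scan summaries."""

    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def max_over_time(self) -> np.ndarray:
        return self.values.max(axis=1)

    def mean_over_time(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def std_over_time(self, ddof: int = 1) -> np.ndarray:
        if self.values.shape[1] < 2:
            raise InputError("std over time requires at least 2 time points")
        return self.values.std(axis=1, ddof=ddof)


@dataclass
class EnergyTensor:
    """E(psi_k, t) = |alpha_k(t)|^2 * lambda_k^2."""

    values: np.ndarray
    eigenvalues: np.ndarray

    @property
    def total_per_timepoint(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean_over_time(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def std_over_time(self, ddof: int = 1) -> np.ndarray:
        return self.values.std(axis=1, ddof=ddof)


def decompose(series: FunctionalSeries, basis: HarmonicBasis) -> SpectralCoefficients:
    """alpha = Psi^T F, one coefficient per (harmonic, time point)."""
    if series.n_vertices != basis.n:
        raise InputError(
            f"series has {series.n_vertices} vertices but basis expects {basis.n}"
        )
    alpha = basis.eigenvectors.T @ series.data
    return SpectralCoefficients(
        alpha=alpha,
        basis_fingerprint=basis.graph_fingerprint,
        subject_id=series.subject_id,
        condition=series.condition,
    )


def reconstruct(coeffs: SpectralCoefficients, basis: HarmonicBasis) -> FunctionalSeries:
    """F_hat = Psi alpha; exact when the basis is complete."""
    if coeffs.m > basis.m:
        raise InputError(f"{coeffs.m} coefficients but basis holds {basis.m} modes")
    if coeffs.basis_fingerprint and basis.graph_fingerprint and (
        coeffs.basis_fingerprint != basis.graph_fingerprint
    ):
        raise IntegrityError("coefficients were computed against a different basis")
    data = basis.eigenvectors[:, : coeffs.m] @ coeffs.alpha
    return FunctionalSeries(data=data)


def power(coeffs: SpectralCoefficients) -> PowerTensor:
    return PowerTensor(values=np.abs(coeffs.alpha))


def energy(coeffs: SpectralCoefficients, basis: HarmonicBasis) -> EnergyTensor:
    if coeffs.m > basis.m:
        raise InputError("eigenvalues unavailable for all coefficient modes")
    if coeffs.basis_fingerprint and basis.graph_fingerprint and (
        coeffs.basis_fingerprint != basis.graph_fingerprint
    ):
        raise IntegrityError("coefficients were computed against a different basis")
    lam = basis.eigenvalues[: coeffs.m]
    values = (coeffs.alpha**2) * (lam[:, None] ** 2)
    return EnergyTensor(values=values, eigenvalues=lam.copy())


def zscore_vertices(series: FunctionalSeries) -> tuple[FunctionalSeries, int]:
    """Standardize each vertex time course (mean 0, sd 1, ddof=1).

    Constant vertices are zeroed; their count is returned alongside.
    """
    if series.n_timepoints < 2:
        raise InputError("z-scoring requires at least 2 time points")
    mean = series.data.mean(axis=1, keepdims=True)
    sd = series.data.std(axis=1, ddof=1, keepdims=True)
    constant = sd.ravel() == 0
    sd[constant] = 1.0
    out = (series.data - mean) / sd
    out[constant] = 0.0
    z = FunctionalSeries(
        data=out,
        tr=series.tr,
        subject_id=series.subject_id,
        condition=series.condition,
        scan_order=series.scan_order,
    )
    return z, int(constant.sum())


# ---------------------------------------------------------------------------
# Coefficient container I/O


def save_coeffs(coeffs: SpectralCoefficients, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("alpha", data=coeffs.alpha)
        fh.attrs["basis_fingerprint"] = coeffs.basis_fingerprint
        fh.attrs["preprocessing"] = coeffs.preprocessing
        fh.attrs["subject_id"] = coeffs.subject_id or ""
        fh.attrs["condition"] = coeffs.condition or ""


def load_coeffs(path) -> SpectralCoefficients:
    import h5py

    try:
        with h5py.File(path, "r") as fh:
            return SpectralCoefficients(
                alpha=fh["alpha"][...],
                basis_fingerprint=str(fh.attrs.get("basis_fingerprint", "")),
                preprocessing=str(fh.attrs.get("preprocessing", "raw")),
                subject_id=str(fh.attrs.get("subject_id", "")) or None,
                condition=str(fh.attrs.get("condition", "")) or None,
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"{path}: not a readable coefficients file") from exc


# ---------------------------------------------------------------------------
# TSV I/O (vertices as rows, time as columns)


def write_functional_tsv(series: FunctionalSeries, path) -> None:
    with open(path, "w") as fh:
        tr = series.tr if series.tr is not None else "nan"
        fh.write(
            f"# n={series.n_vertices} T={series.n_timepoints} TR={tr}\n"
        )
        np.savetxt(fh, series.data, delimiter="\t", fmt="%.17g")


def read_functional_tsv(path) -> FunctionalSeries:
    tr = None
    header = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            header = first
        else:
            fh.seek(0)
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed functional TSV") from exc
    if header is not None:
        for tok in header.lstrip("#").split():
            if tok.startswith("TR="):
                val = tok[3:]
                tr = None if val == "nan" else float(val)
            elif tok.startswith("n="):
                if int(tok[2:]) != data.shape[0]:
                    raise FormatError(f"{path}: header n does not match row count")
            elif tok.startswith("T="):
                if int(tok[2:]) != data.shape[1]:
                    raise FormatError(f"{path}: header T does not match column count")
    return FunctionalSeries(data=data, tr=tr)
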