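"""Cross-frequency co-activation: correlations between |alpha_k(t)| courses.

"Frequency" here is spatial wavenumber, not temporal Hz. Bands are fractional
ranges of the spectrum (defaults (0, .01], (.01, .1], (.1, .2], (.2, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import SpectralCoefficients
from .errors import InputError
from .stats import cohens_d

DEFAULT_BANDS = ((0.0, 0.01), (0.01, 0.1), (0.1, 0.2), (0.2, 1.0))

__all__ = [
    "CrossFreqMatrix",
    "crossfreq_matrix",
    "band_indices",
    "band_values",
    "partition_means",
    "band_contrast",
    "DEFAULT_BANDS",
]


@dataclass
class CrossFreqMatrix:
    """m x m Pearson correlations of absolute coefficient time courses.

    Zero-variance harmonics have undefined correlations, stored as NaN and
    excluded (with counts) from every aggregate.
    """

    r: np.ndarray
    n_missing_rows: int = 0

    @property
    def m(self) -> int:
        return self.r.shape[0]


def crossfreq_matrix(coeffs: SpectralCoefficients | np.ndarray) -> CrossFreqMatrix:
    alpha = coeffs.alpha if isinstance(coeffs, SpectralCoefficients) else np.asarray(coeffs)
    if alpha.shape[1] < 3:
        raise InputError("need at least 3 time points for correlations")
    p = np.abs(alpha)
    sd = p.std(axis=1)
    valid = sd > 0
    r = np.full((p.shape[0], p.shape[0]), np.nan)
    if valid.any():
        r_valid = np.corrcoef(p[valid])
        r_valid = np.atleast_2d(r_valid)
        ix = np.flatnonzero(valid)
        r[np.ix_(ix, ix)] = r_valid
        r[ix, ix] = 1.0
    return CrossFreqMatrix(r=r, n_missing_rows=int((~valid).sum()))


def band_indices(m: int, band: tuple[float, float]) -> np.ndarray:
    """0-based harmonic indices of a fractional band (lo, hi] of the spectrum.

    Wavenumbers selected are ``ceil(lo*m)+1 .. floor(hi*m)`` (1-based).
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 1.0):
        raise InputError(f"band fractions must satisfy 0 <= lo < hi <= 1, got {band}")
    first = int(np.ceil(lo * m)) + 1
    last = int(np.floor(hi * m))
    if first > last:
        raise InputError(f"band {band} selects no harmonics for m={m}")
    return np.arange(first - 1, last)


def band_values(
    matrix: CrossFreqMatrix,
    band: tuple[float, float],
    other_band: tuple[float, float] | None = None,
) -> np.ndarray:
    """Correlation values within a band (upper triangle, diagonal excluded)
    or between two disjoint bands (full cross block). NaNs are dropped."""
    idx = band_indices(matrix.m, band)
    if other_band is None:
        block = matrix.r[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        vals = block[iu]
    else:
        jdx = band_indices(matrix.m, other_band)
        if np.intersect1d(idx, jdx).size:
            raise InputError("between-band extraction requires disjoint bands")
        vals = matrix.r[np.ix_(idx, jdx)].ravel()
    return vals[~np.isnan(vals)]


def partition_means(matrix: CrossFreqMatrix, p: int = 10) -> np.ndarray:
    """p x p block means over contiguous equal-count spectrum partitions.

    The remainder goes to the last block; the matrix diagonal is excluded from
    diagonal blocks; NaN entries are excluded everywhere.
    """
    m = matrix.m
    if m < p:
        raise InputError(f"spectrum of {m} harmonics cannot form {p} partitions")
    size = m // p
    bounds = [(i * size, (i + 1) * size if i < p - 1 else m) for i in range(p)]
    r = matrix.r.copy()
    out = np.empty((p, p))
    for i, (a0, a1) in enumerate(bounds):
        for j, (b0, b1) in enumerate(bounds):
            block = r[a0:a1, b0:b1]
            if i == j:
                block = block.copy()
                np.fill_diagonal(block, np.nan)
            with np.errstate(invalid="ignore"):
                out[i, j] = np.nanmean(block)
    return out


def band_contrast(
    matrices_by_condition: dict,
    band: tuple[float, float],
    condition_pair: tuple[str, str],
    d_threshold: float = 0.2,
) -> dict:
    """Cohen's d between two conditions' pooled within-band correlation values.

    ``condition_pair = (baseline, test)``; d > 0 means larger correlations in
    the test condition. Flagged when |d| >= ``d_threshold``.
    """
    base, test = condition_pair
    for cond in condition_pair:
        if cond not in matrices_by_condition:
            raise InputError(f"condition {cond!r} missing")

    def pooled(cond):
        mats = matrices_by_condition[cond]
        if not isinstance(mats, (list, tuple)):
            mats = [mats]
        vals = np.concatenate([band_values(m, band) for m in mats])
        if len(vals) == 0:
            raise InputError(f"no band values for condition {cond!r}")
        return vals

    a, b = pooled(test), pooled(base)
    d = cohens_d(a, b)
    return {
        "band": band,
        "cohens_d": d,
        "significant": abs(d) >= d_threshold,
        "n_test": len(a),
        "n_baseline": len(b),
    }
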