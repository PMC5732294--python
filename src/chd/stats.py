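"""Group-comparison statistics shared by the analysis modules.

Provides two-sample t and KS tests, a paired label-permutation test with the
add-one p rule (exhaustively enumerable for small n), Bonferroni correction,
Cohen's d, rating correlations, and the multiple correlation coefficient in
its direct and harmonic-mediated (indirect) forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import scipy.stats

from .errors import InputError

__all__ = [
    "ConditionComparison",
    "ttest2",
    "kstest2",
    "permutation_test",
    "bonferroni",
    "cohens_d",
    "energy_rating_correlation",
    "multiple_correlation",
    "indirect_multiple_correlation",
]


@dataclass
class ConditionComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    correction: str = "none"
    effect_size: float | None = None
    notes: list[str] = field(default_factory=list)


def _asarray(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if not np.isfinite(arr).all():
        raise InputError(f"{name} contains non-finite values")
    return arr


def ttest2(a, b) -> ConditionComparison:
    """Two-sample (pooled-variance) t-test, two-sided."""
    a, b = _asarray(a, "a"), _asarray(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 observations")
    notes = []
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return ConditionComparison(0.0, 1.0, len(a), len(b), notes=["degenerate: zero variance, equal means"])
        notes.append("degenerate: zero variance, unequal means")
        return ConditionComparison(np.inf, 0.0, len(a), len(b), notes=notes)
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return ConditionComparison(float(t), float(p), len(a), len(b))


def kstest2(a, b) -> ConditionComparison:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a, b = _asarray(a, "a"), _asarray(b, "b")
    if len(a) < 5 or len(b) < 5:
        raise InputError("each group needs at least 5 observations for the KS test")
    d, p = scipy.stats.ks_2samp(a, b, method="asymp")
    return ConditionComparison(float(d), float(p), len(a), len(b))


def permutation_test(
    a_by_subject,
    b_by_subject,
    n_perm: int = 10000,
    seed: int | None = None,
    exact: bool = False,
) -> ConditionComparison:
    """Paired label-permutation test on the mean within-subject difference.

    The null is built by swapping the two condition labels within each subject
    (sign-flipping the paired differences); p uses the add-one rule
    ``(1 + #{|null| >= |obs|}) / (n_perm + 1)`` and is therefore never below
    ``1 / (n_perm + 1)``. With ``exact=True`` all 2^n flip patterns are
    enumerated instead (no add-one correction needed; the identity pattern is
    part of the enumeration).
    """
    a, b = _asarray(a_by_subject, "a"), _asarray(b_by_subject, "b")
    if len(a) != len(b):
        raise InputError("paired design requires equal-length condition vectors")
    if len(a) < 2:
        raise InputError("need at least 2 subject pairs")
    diffs = a - b
    obs = diffs.mean()
    n = len(diffs)
    if exact:
        if n > 20:
            raise InputError("exhaustive enumeration limited to n <= 20 pairs")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        null = signs @ diffs / n
        p = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
        return ConditionComparison(float(obs), p, n, n, notes=["exact enumeration"])
    if n_perm < 100:
        raise InputError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null = signs @ diffs / n
    hits = int(np.sum(np.abs(null) >= abs(obs) - 1e-12))
    p = (1.0 + hits) / (n_perm + 1.0)
    return ConditionComparison(float(obs), float(p), n, n)


def bonferroni(p_values, k: int, alpha: float = 0.01):
    """Adjusted p = min(1, p*k) and decisions at ``alpha``."""
    p = np.asarray(p_values, dtype=np.float64)
    if k < len(p):
        raise InputError(f"correction factor k={k} smaller than number of tests {len(p)}")
    adjusted = np.minimum(1.0, p * k)
    return adjusted, adjusted < alpha


def cohens_d(a, b) -> float:
    """(mean a - mean b) / pooled SD with (n-1) weights."""
    a, b = _asarray(a, "a"), _asarray(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise InputError("pooled SD is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def energy_rating_correlation(energy_changes, ratings) -> ConditionComparison:
    """Pearson correlation between per-scan energy changes and ratings."""
    x, y = _asarray(energy_changes, "energy_changes"), _asarray(ratings, "ratings")
    if len(x) != len(y):
        raise InputError("energy changes and ratings must align one-to-one")
    if len(x) < 4:
        raise InputError("need at least 4 subject-scan pairs")
    r, p = scipy.stats.pearsonr(x, y)
    return ConditionComparison(float(r), float(p), len(x), len(y))


def multiple_correlation(predictors, response) -> ConditionComparison:
    """Multiple correlation R = sqrt(c' Rxx^-1 c) with an F-test on R^2.

    ``c`` is the vector of simple predictor-response correlations and ``Rxx``
    the predictor intercorrelation matrix; degrees of freedom (q, n - q - 1).
    """
    x = np.asarray(predictors, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    y = _asarray(response, "response")
    n, q = x.shape
    if len(y) != n:
        raise InputError("predictor rows must match response length")
    if n <= q + 1:
        raise InputError(f"need more than q+1={q + 1} observations, got {n}")
    if (x.std(axis=0) == 0).any() or y.std() == 0:
        raise InputError("constant predictor or response; correlation undefined")
    c = np.array([scipy.stats.pearsonr(x[:, j], y)[0] for j in range(q)])
    rxx = np.corrcoef(x, rowvar=False).reshape(q, q)
    if np.linalg.cond(rxx) > 1e12:
        raise InputError("predictor intercorrelation matrix is singular (collinearity)")
    r2 = float(c @ np.linalg.solve(rxx, c))
    r2 = min(max(r2, 0.0), 1.0)
    big_r = np.sqrt(r2)
    dof2 = n - q - 1
    if r2 >= 1.0:
        p = 0.0
    else:
        f = (r2 / q) / ((1.0 - r2) / dof2)
        p = float(scipy.stats.f.sf(f, q, dof2))
    return ConditionComparison(big_r, p, n, n)


def harmonic_correlate_representation(vector, energy_change_matrix, n_harmonics: int) -> np.ndarray:
    """Re-express an observation vector as correlations with per-harmonic
    energy-change vectors (the first ``n_harmonics`` columns)."""
    v = _asarray(vector, "vector")
    e = np.asarray(energy_change_matrix, dtype=np.float64)
    if e.ndim != 2 or e.shape[0] != len(v):
        raise InputError("energy-change matrix must be (n_obs, n_harmonics_available)")
    if n_harmonics < 1 or n_harmonics > e.shape[1]:
        raise InputError(f"n_harmonics must lie in [1, {e.shape[1]}]")
    out = np.empty(n_harmonics)
    for k in range(n_harmonics):
        col = e[:, k]
        if col.std() == 0 or v.std() == 0:
            out[k] = 0.0
        else:
            out[k] = scipy.stats.pearsonr(v, col)[0]
    return out


def indirect_multiple_correlation(
    rsn_change_vectors,
    rating_vector,
    energy_change_matrix,
    n_harmonics: int,
) -> ConditionComparison:
    """Multiple correlation on harmonic-correlate representations.

    Each observation vector (per-network connectivity change, rating) is first
    replaced by its length-``n_harmonics`` vector of correlations with the
    per-harmonic energy-change vectors; the multiple correlation is computed
    over that representation, treating harmonic correlates as samples. A
    warning is always attached: those correlates are not independent samples,
    so the attached p-value should be read qualitatively.
    """
    x = np.asarray(rsn_change_vectors, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    q = x.shape[1]
    if n_harmonics < q + 2:
        raise InputError(
            f"n_harmonics={n_harmonics} must be at least number of networks + 2 = {q + 2}"
        )
    reps = np.column_stack(
        [
            harmonic_correlate_representation(x[:, j], energy_change_matrix, n_harmonics)
            for j in range(q)
        ]
    )
    y_rep = harmonic_correlate_representation(rating_vector, energy_change_matrix, n_harmonics)
    result = multiple_correlation(reps, y_rep)
    note = (
        "harmonic correlates are treated as observations; they are not "
        "independent samples, so the p-value is heuristic"
    )
    warnings.warn(note, stacklevel=2)
    result.notes.append(note)
    return result
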