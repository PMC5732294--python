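"""Power-law diagnostics of the power spectrum versus wavenumber.

Max/mean/std power per harmonic are log-binned (default 100 bins) and fitted
with an ordinary least-squares line in log10-log10 space. The slope is the
critical exponent beta; the RMSE of the residuals (in log10 units) is the
goodness-of-fit epsilon — smaller epsilon means closer to a pure power law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import PowerTensor
from .errors import InputError
from .stats import ttest2

__all__ = [
    "PowerLawFit",
    "power_summaries",
    "log_bin",
    "fit_power_law",
    "compare_fits",
]

SUMMARY_KINDS = ("max", "mean", "std")


@dataclass
class PowerLawFit:
    beta: float
    intercept: float
    epsilon: float
    n_bins: int
    summary_kind: str = ""


def power_summaries(p: PowerTensor) -> dict[str, np.ndarray]:
    """Per-harmonic max, mean and std (ddof=1) of power over time."""
    if p.values.shape[1] < 2:
        raise InputError("power summaries require at least 2 time points")
    return {
        "max": p.max_over_time(),
        "mean": p.mean_over_time(),
        "std": p.std_over_time(),
    }


def log_bin(
    x, y, n_bins: int = 100
) -> tuple[np.ndarray, np.ndarray, int]:
    """Logarithmic binning: geometric-mean abscissa, arithmetic-mean ordinate.

    Points with y == 0 are excluded (their count is returned); empty bins are
    dropped. Needs at least 3 non-empty bins.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise InputError("x and y must align")
    if (x < 1).any():
        raise InputError("wavenumbers must be >= 1")
    if (y < 0).any():
        raise InputError("series values must be non-negative")
    keep = y > 0
    n_zero = int((~keep).sum())
    x, y = x[keep], y[keep]
    if len(x) == 0:
        raise InputError("no positive values to bin")
    edges = 10.0 ** np.linspace(np.log10(x.min()), np.log10(x.max()), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sum_logx = np.bincount(idx, weights=np.log10(x), minlength=n_bins)
    sum_y = np.bincount(idx, weights=y, minlength=n_bins)
    occupied = counts > 0
    if occupied.sum() < 3:
        raise InputError("fewer than 3 non-empty bins")
    xbar = 10.0 ** (sum_logx[occupied] / counts[occupied])
    ybar = sum_y[occupied] / counts[occupied]
    return xbar, ybar, n_zero


def fit_power_law(
    xbar, ybar, summary_kind: str = ""
) -> PowerLawFit:
    """OLS line fit of log10(y) on log10(x): beta = slope, epsilon = RMSE."""
    xbar = np.asarray(xbar, dtype=np.float64).ravel()
    ybar = np.asarray(ybar, dtype=np.float64).ravel()
    if len(xbar) < 3:
        raise InputError("need at least 3 binned points")
    if (xbar <= 0).any() or (ybar <= 0).any():
        raise InputError("log fit requires strictly positive binned values")
    lx, ly = np.log10(xbar), np.log10(ybar)
    beta, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (beta * lx + intercept)
    epsilon = float(np.sqrt(np.mean(resid**2)))
    return PowerLawFit(
        beta=float(beta),
        intercept=float(intercept),
        epsilon=epsilon,
        n_bins=len(xbar),
        summary_kind=summary_kind,
    )


def fit_scan(p: PowerTensor, n_bins: int = 100) -> dict[str, PowerLawFit]:
    """Power-law fits of all three power summaries of one scan."""
    k = np.arange(1, p.values.shape[0] + 1, dtype=np.float64)
    out = {}
    for kind, series in power_summaries(p).items():
        xbar, ybar, _ = log_bin(k, series, n_bins=n_bins)
        out[kind] = fit_power_law(xbar, ybar, summary_kind=kind)
    return out


def compare_fits(
    fits: pd.DataFrame, condition_pair: tuple[str, str]
) -> pd.DataFrame:
    """Two-sample t-tests on per-subject beta and epsilon between conditions.

    ``fits`` is a long table with columns subject, condition, summary_kind,
    beta, epsilon. Returns one row per (summary_kind, parameter) with the
    mean difference (test minus baseline), t and p.
    """
    base, test = condition_pair
    rows = []
    for kind in sorted(fits["summary_kind"].unique()):
        sub = fits[fits["summary_kind"] == kind]
        a = sub[sub["condition"] == base]
        b = sub[sub["condition"] == test]
        if len(a) < 2 or len(b) < 2:
            raise InputError(
                f"need at least 2 fits per condition for summary {kind!r}"
            )
        for param in ("beta", "epsilon"):
            res = ttest2(b[param].to_numpy(), a[param].to_numpy())
            rows.append(
                {
                    "summary_kind": kind,
                    "parameter": param,
                    "delta": float(b[param].mean() - a[param].mean()),
                    "t": res.statistic,
                    "p": res.p_value,
                }
            )
    return pd.DataFrame(rows)
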