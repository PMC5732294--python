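"""Synthetic functional series with known spectral ground truth.

Coefficients are drawn per harmonic with a power-law magnitude profile,
optional band modulations, optional within-band coupling through a shared
latent course, then lifted to vertex space through the basis plus white
noise. A study generator produces paired two-condition, multi-subject
datasets with planted effects: low-k suppression, high-k boost, repertoire
widening and high-band coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crossfreq import band_indices
from .decomposition import FunctionalSeries
from .errors import ConfigError, InputError
from .harmonics import HarmonicBasis

__all__ = [
    "SpectralProfile",
    "CouplingSpec",
    "StudyDesign",
    "generate_series",
    "generate_study",
    "expected_repertoire_ratio",
]


@dataclass
class SpectralProfile:
    """Target magnitude profile: SD of alpha_k follows C * k^(-exponent)."""

    exponent: float = 1.0
    amplitude: float = 1.0
    cutoff_k: float | None = None
    band_modulations: tuple = ()  # ((lo_frac, hi_frac), factor) pairs

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be positive")
        for band, factor in self.band_modulations:
            if factor <= 0:
                raise ConfigError(f"band factor must be positive, got {factor}")

    def sd_per_harmonic(self, m: int) -> np.ndarray:
        k = np.arange(1, m + 1, dtype=np.float64)
        sd = self.amplitude * k ** (-self.exponent)
        if self.cutoff_k is not None:
            sd *= np.exp(-k / self.cutoff_k)
        for band, factor in self.band_modulations:
            try:
                idx = band_indices(m, band)
            except InputError:
                continue  # band inactive at this spectral resolution
            sd[idx] *= factor
        return sd


@dataclass
class CouplingSpec:
    """Share a latent time course across a band with the given mixing weight."""

    band: tuple[float, float] = (0.2, 1.0)
    weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight < 1.0:
            raise ConfigError("coupling weight must lie in [0, 1)")


def generate_series(
    basis: HarmonicBasis,
    profile: SpectralProfile,
    T: int,
    noise_sd: float,
    seed,
    coupling: CouplingSpec | None = None,
    distribution: str = "normal",
) -> tuple[FunctionalSeries, np.ndarray]:
    """One scan: F = Psi alpha + noise, returning the ground-truth alpha.

    ``distribution="normal"`` draws alpha_k(t) ~ N(0, sd_k^2) (so |alpha| is
    half-normal); ``"lognormal"`` draws magnitudes log-normally with median
    sd_k and a random sign.
    """
    if T < 2:
        raise InputError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    m = basis.m
    sd = profile.sd_per_harmonic(m)
    z = rng.standard_normal((m, T))
    if coupling is not None:
        idx = band_indices(m, coupling.band)
        latent = rng.standard_normal(T)
        w = coupling.weight
        z[idx] = np.sqrt(1.0 - w**2) * z[idx] + w * latent
    if distribution == "normal":
        alpha = sd[:, None] * z
    elif distribution == "lognormal":
        signs = rng.choice((-1.0, 1.0), size=(m, T))
        alpha = signs * sd[:, None] * np.exp(0.5 * z)
    else:
        raise ConfigError(f"unknown coefficient distribution {distribution!r}")
    data = basis.eigenvectors @ alpha
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return FunctionalSeries(data=data), alpha


DEFAULT_TEST_MODULATIONS = (((0.0, 0.01), 0.8), ((0.2, 1.0), 1.3))


@dataclass
class StudyDesign:
    """Paired two-condition study emulating a baseline/active-drug contrast.

    Condition B applies ``test_band_modulations`` (default: x0.8 on the lowest
    1% of wavenumbers, x1.3 on the top 80%) on top of the baseline profile,
    optionally widens the whole coefficient distribution (``test_widen``) and
    couples the high band through a shared latent course. Per-subject
    amplitude/exponent jitter is shared across a subject's two scans, so the
    paired contrast sees only the planted effect.
    """

    n_subjects: int = 12
    t_per_scan: int = 100
    noise_sd: float = 0.0
    baseline_profile: SpectralProfile = field(default_factory=SpectralProfile)
    baseline_label: str = "A"
    test_label: str = "B"
    test_band_modulations: tuple = DEFAULT_TEST_MODULATIONS
    test_widen: float = 1.0
    test_coupling: CouplingSpec | None = None
    subject_amplitude_jitter: float = 0.1
    subject_exponent_jitter: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("need at least 1 subject")
        if self.test_widen <= 0:
            raise ConfigError("test_widen must be positive")

    def subject_profiles(self, subject: int) -> tuple[SpectralProfile, SpectralProfile]:
        """Baseline and test profiles for one subject (shared jitter)."""
        rng = np.random.default_rng([self.master_seed, 1000 + subject])
        amp = self.baseline_profile.amplitude * np.exp(
            self.subject_amplitude_jitter * rng.standard_normal()
        )
        expo = self.baseline_profile.exponent + (
            self.subject_exponent_jitter * rng.standard_normal()
        )
        base = replace(self.baseline_profile, amplitude=amp, exponent=expo)
        test = replace(
            base,
            amplitude=amp * self.test_widen,
            band_modulations=tuple(base.band_modulations)
            + tuple(self.test_band_modulations),
        )
        return base, test


def generate_study(basis: HarmonicBasis, design: StudyDesign) -> list[dict]:
    """Paired scans for every subject; each record carries the truth alpha.

    Returns a list of dicts with keys ``subject``, ``condition``, ``series``,
    ``alpha_truth``. Deterministic under the design's master seed.
    """
    records = []
    for s in range(design.n_subjects):
        base_profile, test_profile = design.subject_profiles(s)
        for c, (label, profile, coupling) in enumerate(
            [
                (design.baseline_label, base_profile, None),
                (design.test_label, test_profile, design.test_coupling),
            ]
        ):
            series, alpha = generate_series(
                basis,
                profile,
                design.t_per_scan,
                design.noise_sd,
                seed=[design.master_seed, s, c],
                coupling=coupling,
            )
            series.subject_id = f"S{s:02d}"
            series.condition = label
            records.append(
                {
                    "subject": f"S{s:02d}",
                    "condition": label,
                    "series": series,
                    "alpha_truth": alpha,
                }
            )
    return records


def expected_repertoire_ratio(design: StudyDesign, m: int) -> float:
    """Planted test/baseline ratio of pooled repertoire width.

    With per-harmonic baseline-max normalization, each harmonic's normalized
    values in the test condition scale by its SD ratio f_k, so the pooled
    width scales by sqrt(mean f_k^2).
    """
    base = design.baseline_profile.sd_per_harmonic(m)
    test_profile = replace(
        design.baseline_profile,
        amplitude=design.baseline_profile.amplitude * design.test_widen,
        band_modulations=tuple(design.baseline_profile.band_modulations)
        + tuple(design.test_band_modulations),
    )
    test = test_profile.sd_per_harmonic(m)
    f = test / base
    return float(np.sqrt(np.mean(f**2)))
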