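"""Population-structure PCA and two-proportion power estimation.

PCA standardizes each SNP column by its estimated allele frequency
(center 2*p_hat, scale sqrt(2*p_hat*(1-p_hat))), mean-imputes missing
dosages, and decomposes with an SVD. Power uses the normal approximation
for the two-sided two-proportion test at Cohen's standardized effect h.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix


@dataclass
class PCAResult:
    scores: np.ndarray              # (n_samples, k)
    loadings: np.ndarray            # (n_snps, k)
    variance_explained: np.ndarray  # fractions, nonincreasing, sum <= 1
    snp_means: np.ndarray           # 2*p_hat per SNP
    snp_scales: np.ndarray


def genotype_pca(matrix: GenotypeMatrix, k: int = 10) -> PCAResult:
    """SNP-standardized principal components of the genotype matrix.

    Missing dosages are mean-imputed per SNP before standardization.
    Monomorphic columns (zero variance) get unit scale and contribute
    nothing after centering. Sign convention: the largest-|loading| entry
    of each component is positive. k beyond the matrix rank is truncated
    with a warning.
    """
    D = matrix.dosages.copy()
    p_hat = np.nanmean(D, axis=0) / 2.0
    means = 2.0 * p_hat
    col_nan = np.isnan(D)
    D[col_nan] = np.broadcast_to(means, D.shape)[col_nan]
    scales = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    scales[scales == 0] = 1.0
    Z = (D - means) / scales

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    total = (S ** 2).sum()
    varexp = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PCAResult(scores=scores, loadings=loadings,
                     variance_explained=varexp,
                     snp_means=means, snp_scales=scales)


@dataclass
class PowerSpec:
    """Inputs to the two-proportion power calculation.

    ``effect_size_h`` is Cohen's h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2)).
    """

    effect_size_h: float
    alpha: float
    n_cases: int
    n_controls: int
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.effect_size_h <= 0:
            raise ValueError("effect size h must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def cohens_h(p1: float, p2: float) -> float:
    """Standardized difference of two proportions (arcsine scale)."""
    return float(abs(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2))))


def two_proportion_power(spec: PowerSpec) -> float:
    """Normal-approximation power of the two-proportion test.

    With unequal group sizes the effective size is the harmonic-mean
    n_tilde = 2 n1 n2 / (n1 + n2); two-sided power is
    Phi(h sqrt(n_tilde/2) - z_{1-a/2}) + Phi(-h sqrt(n_tilde/2) - z_{1-a/2}).
    """
    n1, n2 = spec.n_cases, spec.n_controls
    n_tilde = 2.0 * n1 * n2 / (n1 + n2)
    shift = spec.effect_size_h * np.sqrt(n_tilde / 2.0)
    if spec.sided == "two":
        z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
        power = stats.norm.cdf(shift - z) + stats.norm.cdf(-shift - z)
    else:
        z = stats.norm.ppf(1.0 - spec.alpha)
        power = stats.norm.cdf(shift - z)
    return float(power)


def power_for_log_or(log_or: float, maf: float, alpha: float,
                     n_cases: int, n_controls: int) -> float:
    """Power for an allele-frequency shift implied by a log odds ratio.

    Converts the control-allele frequency ``maf`` and per-allele log-OR
    into the case frequency, maps to Cohen's h and reuses the
    two-proportion formula.
    """
    from scipy.special import expit, logit
    p_case = float(expit(logit(maf) + log_or))
    h = cohens_h(maf, p_case)
    return two_proportion_power(PowerSpec(h, alpha, n_cases, n_controls))
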