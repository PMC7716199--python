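"""Per-SNP association: allelic chi-square tests and covariate-adjusted
additive logistic regression, with Benjamini-Hochberg FDR control.

The logistic fits use iteratively reweighted least squares (equivalently
Newton-Raphson with the expected information), converging when the maximum
absolute score drops below 1e-8 or the relative log-likelihood change
drops below 1e-10, capped at 50 iterations. Complete (quasi-)separation is
flagged rather than penalized: a non-converged fit with any |beta| > 15
reports p = NaN.

A batched variant fits one model per SNP simultaneously (shared covariates,
per-SNP dosage column and missingness mask); it is the engine behind both
the full-sample scan and the randomized sub-sampling scans.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .containers import GenotypeMatrix, PhenotypeTable
from .io_config import RunConfig

SCORE_TOL = 1e-8
LL_REL_TOL = 1e-10
MAX_ITER = 50
SEPARATION_BETA = 15.0

#: Covariates entering every adjusted model: age, BMI and the European
#: ancestry proportion (one component of the simplex to avoid collinearity).
ADJUST_COVARIATES = ("age", "bmi", "anc_eur")


# ---------------------------------------------------------------------------
# Allelic test
# ---------------------------------------------------------------------------

def allelic_test(dosages: np.ndarray, status: np.ndarray
                 ) -> tuple[float, float, float]:
    """Pearson chi-square on the 2x2 allele-count table.

    Returns (chi2, p, allelic OR). The OR uses the Haldane-Anscombe +0.5
    adjustment on all cells iff any cell is zero. No continuity correction.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    table = np.zeros((2, 2))  # rows: case/control, cols: minor/major
    for row, grp in ((0, y == 1), (1, y == 0)):
        dg = d[grp]
        dg = dg[np.isfinite(dg)]
        if dg.size == 0:
            raise ValueError("allelic test: a group has no non-missing genotypes")
        minor = dg.sum()
        table[row] = (minor, 2 * dg.size - minor)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    if (expected == 0).any():   # a monomorphic SNP: no allelic information
        chi2, p = 0.0, 1.0
    else:
        chi2 = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    t = table + 0.5 if (table == 0).any() else table
    or_allelic = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return chi2, p, or_allelic


# ---------------------------------------------------------------------------
# Logistic regression (scalar)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta: float          # coefficient on the dosage term
    se: float
    p: float             # two-sided Wald; NaN when separated
    converged: bool
    separated: bool
    n_used: int
    params: np.ndarray   # full coefficient vector (intercept first)
    se_all: np.ndarray


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit. Returns (beta, covariance, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll = _loglik(X, y, beta)
    converged = False
    for _ in range(MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        w = mu * (1 - mu)
        xtwx = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(xtwx, score, rcond=None)[0]
        # step-halving keeps the likelihood ascent monotone
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        if abs(ll_new - ll) < LL_REL_TOL * (abs(ll) + 1e-12):
            # a stall with runaway coefficients is separation, not a fit
            converged = np.abs(beta).max() <= SEPARATION_BETA
            ll = ll_new
            break
        ll = ll_new
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-12)
    xtwx = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    if not converged and np.abs(X.T @ (y - mu)).max() < SCORE_TOL:
        converged = True
    return beta, cov, converged


def fit_logistic(dosage: np.ndarray, covariates: np.ndarray,
                 status: np.ndarray) -> LogisticFit:
    """Additive logistic model status ~ dosage + covariates (complete case).

    The reported beta/se/p are for the dosage term. Separation yields a
    flagged result with p = NaN, never an exception; a rank-deficient
    design raises, naming the collinear columns.
    """
    d = np.asarray(dosage, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != d.shape[0]:
        C = C.T
    y = np.asarray(status, dtype=float)
    ok = np.isfinite(d) & np.isfinite(C).all(axis=1) & np.isfinite(y)
    d, C, y = d[ok], C[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class after complete-case filtering")
    X = np.column_stack([np.ones(d.size), d, C])
    names = ["intercept", "dosage"] + [f"cov{i}" for i in range(C.shape[1])]
    _check_rank(X, names)
    beta, cov, converged = _irls(X, y)
    # runaway coefficients mean (quasi-)separation even when the flat
    # likelihood lets the score criterion trigger
    separated = bool(np.abs(beta).max() > SEPARATION_BETA)
    se = np.sqrt(np.diag(cov))
    if separated:
        p = np.nan
    else:
        z = beta[1] / se[1]
        p = float(2 * stats.norm.sf(abs(z)))
    return LogisticFit(beta=float(beta[1]), se=float(se[1]), p=p,
                       converged=converged, separated=separated,
                       n_used=int(d.size), params=beta, se_all=se)


# ---------------------------------------------------------------------------
# Logistic regression (batched over SNPs)
# ---------------------------------------------------------------------------

def fit_logistic_many(dosages: np.ndarray, covariates: np.ndarray,
                      status: np.ndarray) -> pd.DataFrame:
    """Fit status ~ dosage_j + covariates for every column j of ``dosages``.

    Complete-case per SNP is realized through per-SNP observation weights;
    rows with missing covariates or status are excluded everywhere.
    Returns a DataFrame with beta, se, p, converged, separated, n_used.
    """
    D = np.asarray(dosages, dtype=float)
    if D.ndim == 1:
        D = D[:, None]
    C = np.asarray(covariates, dtype=float)
    y_full = np.asarray(status, dtype=float)
    base_ok = np.isfinite(C).all(axis=1) & np.isfinite(y_full)
    D, C, y = D[base_ok], C[base_ok], y_full[base_ok]
    n, m = D.shape
    p = C.shape[1] + 2
    w = np.isfinite(D).T.astype(float)          # (m, n)
    Dz = np.nan_to_num(D, nan=0.0)
    X = np.empty((m, n, p))
    X[:, :, 0] = 1.0
    X[:, :, 1] = Dz.T
    X[:, :, 2:] = np.broadcast_to(C, (m, n, C.shape[1]))

    beta = np.zeros((m, p))
    ll = np.full(m, -np.inf)
    done = np.zeros(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    for _ in range(MAX_ITER):
        eta = np.clip(np.einsum("mnp,mp->mn", X, beta), -30, 30)
        mu = expit(eta)
        resid = (y[None, :] - mu) * w
        score = np.einsum("mnp,mn->mp", X, resid)
        newly = np.abs(score).max(axis=1) < SCORE_TOL
        converged |= newly
        done |= newly
        if done.all():
            break
        wt = mu * (1 - mu) * w
        xtwx = np.einsum("mnp,mn,mnq->mpq", X, wt, X)
        # tiny ridge guards exactly-singular batches (separated SNPs)
        ridge = 1e-12 * np.trace(xtwx, axis1=1, axis2=2) / p
        xtwx[:, np.arange(p), np.arange(p)] += ridge[:, None]
        delta = np.linalg.solve(xtwx, score[..., None])[..., 0]
        delta[done] = 0.0
        step = np.ones(m)
        ll_cur = np.einsum("mn,mn->m", w, y[None, :] * eta - np.logaddexp(0.0, eta))
        for _ in range(25):
            cand = beta + step[:, None] * delta
            eta_c = np.clip(np.einsum("mnp,mp->mn", X, cand), -30, 30)
            ll_new = np.einsum("mn,mn->m", w,
                               y[None, :] * eta_c - np.logaddexp(0.0, eta_c))
            worse = (~done) & (ll_new < ll_cur - 1e-12)
            if not worse.any():
                break
            step[worse] /= 2.0
        beta = beta + step[:, None] * delta
        stalled = (~done) & (np.abs(ll_new - ll_cur)
                             < LL_REL_TOL * (np.abs(ll_cur) + 1e-12))
        converged |= stalled & (np.abs(beta).max(axis=1) <= SEPARATION_BETA)
        done |= stalled
        ll = ll_new

    eta = np.clip(np.einsum("mnp,mp->mn", X, beta), -30, 30)
    mu = expit(eta)
    score = np.einsum("mnp,mn->mp", X, (y[None, :] - mu) * w)
    converged |= np.abs(score).max(axis=1) < SCORE_TOL
    wt = np.maximum(mu * (1 - mu), 1e-12) * w
    xtwx = np.einsum("mnp,mn,mnq->mpq", X, wt, X)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            cov = np.full_like(xtwx, np.nan)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    separated = np.abs(beta).max(axis=1) > SEPARATION_BETA
    z = beta[:, 1] / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    pvals[separated] = np.nan
    return pd.DataFrame({
        "beta": beta[:, 1], "se": se, "p": pvals,
        "converged": converged, "separated": separated,
        "n_used": w.sum(axis=1).astype(int),
    })


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned to the input order.

    NaNs are excluded from the number of tests m and stay NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]   # monotone step-up
    ranked = np.minimum(ranked, 1.0)
    qs = np.empty(m)
    qs[order] = ranked
    q[ok] = qs
    return q


# ---------------------------------------------------------------------------
# Full-sample scan
# ---------------------------------------------------------------------------

def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def run_scan(matrix: GenotypeMatrix, pheno: PhenotypeTable,
             config: RunConfig | None = None) -> pd.DataFrame:
    """Allelic + adjusted association for every SNP, BH-corrected.

    One row per SNP, sorted by genomic position. Per-SNP failures are
    flagged in place; the scan never aborts for one bad SNP.
    """
    pheno = pheno.subset(matrix.samples)
    y = pheno.y
    order = sorted(range(matrix.n_snps),
                   key=lambda j: (_chrom_key(matrix.snps[j].chromosome),
                                  matrix.snps[j].position))
    matrix = matrix.take_snps(order)
    covs = pheno.covariate_matrix(ADJUST_COVARIATES)

    rows = []
    for j, snp in enumerate(matrix.snps):
        d = matrix.dosages[:, j]
        rec = {"snp_id": snp.snp_id, "chromosome": snp.chromosome,
               "position": snp.position,
               "allele_minor": snp.allele_minor, "allele_major": snp.allele_major}
        try:
            rec["maf_controls"] = compute_coded_freq(d[y == 0])
            rec["maf_cases"] = compute_coded_freq(d[y == 1])
            chi2, ap, aor = allelic_test(d, y)
            rec.update(allelic_chi2=chi2, allelic_p=ap, or_allelic=aor)
        except ValueError as exc:
            rec.update(maf_controls=np.nan, maf_cases=np.nan,
                       allelic_chi2=np.nan, allelic_p=np.nan,
                       or_allelic=np.nan, note=str(exc))
        rows.append(rec)
    result = pd.DataFrame(rows)

    fits = fit_logistic_many(matrix.dosages, covs, y)
    result["beta"] = fits["beta"].to_numpy()
    result["se"] = fits["se"].to_numpy()
    with np.errstate(over="ignore"):   # separated fits can overflow to inf
        result["or_adj"] = np.exp(result["beta"])
        result["ci95_low"] = np.exp(result["beta"] - 1.96 * result["se"])
        result["ci95_high"] = np.exp(result["beta"] + 1.96 * result["se"])
    result["p_adj_model"] = fits["p"].to_numpy()
    result["converged"] = fits["converged"].to_numpy()
    result["separated"] = fits["separated"].to_numpy()
    result["n_used"] = fits["n_used"].to_numpy()
    result["q_fdr"] = bh_fdr(result["p_adj_model"].to_numpy())
    return result


def compute_coded_freq(dosages: np.ndarray) -> float:
    """Frequency of the coded (minor) allele within one group, unfolded."""
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(d)
    if ok.sum() == 0:
        raise ValueError("no non-missing genotypes in group")
    return float(d[ok].sum() / (2.0 * ok.sum()))
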