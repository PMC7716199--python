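"""Randomized matched sub-sampling (RDM) inference.

Confounder imbalance between cases and controls is neutralized by drawing
many case/control sub-samples without replacement, discarding any whose
cases and controls differ significantly (chi-square for ordinal variables,
Welch t for continuous) in the matching variables, re-testing every SNP
within each accepted sub-sample with the covariate-adjusted logistic
model, and keeping a unit when the fraction of significant sub-samples
exceeds the retention threshold (default: strict > 50%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import ADJUST_COVARIATES, fit_logistic_many
from .containers import GenotypeMatrix, PhenotypeTable
from .io_config import RunConfig
from .qc import compute_maf

#: Variables every accepted sub-sample must be balanced on by default.
DEFAULT_MATCH_VARIABLES = ("age", "education", "ses")

#: Variables treated as continuous (Welch t); all others use chi-square.
CONTINUOUS_VARIABLES = frozenset({"age", "bmi"})

ATTEMPT_BUDGET_FACTOR = 100


@dataclass
class SubsampleEnsemble:
    """Accepted balanced sub-samples and their balance diagnostics."""

    subsamples: list[tuple[np.ndarray, np.ndarray]]   # (case ids, control ids)
    balance_p: list[dict[str, float]]
    variables: tuple[str, ...]
    n_attempted: int

    @property
    def n_accepted(self) -> int:
        return len(self.subsamples)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_attempted if self.n_attempted else np.nan


def draw_subsample(case_ids, control_ids, n_cases_sub: int,
                   n_controls_sub: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Simple random sample without replacement from each group."""
    case_ids = np.asarray(case_ids)
    control_ids = np.asarray(control_ids)
    if n_cases_sub > case_ids.size or n_controls_sub > control_ids.size:
        raise ValueError(
            f"requested sub-sample ({n_cases_sub}+{n_controls_sub}) exceeds "
            f"group sizes ({case_ids.size} cases, {control_ids.size} controls)")
    return (rng.choice(case_ids, size=n_cases_sub, replace=False),
            rng.choice(control_ids, size=n_controls_sub, replace=False))


def balance_check(subsample: tuple[np.ndarray, np.ndarray],
                  pheno: PhenotypeTable,
                  variables=DEFAULT_MATCH_VARIABLES,
                  alpha: float = 0.05) -> tuple[dict[str, float], bool]:
    """Case-control balance within one sub-sample.

    Continuous variables use the Welch two-sample t-test, ordinal ones a
    Pearson chi-square on the level x status table (no continuity
    correction). A variable constant within the sub-sample is treated as
    balanced (p = 1) with a warning. Accept iff min p >= alpha.
    """
    case_ids, control_ids = subsample
    pvals: dict[str, float] = {}
    for var in variables:
        a = pheno.data.loc[list(case_ids), var].to_numpy(dtype=float)
        b = pheno.data.loc[list(control_ids), var].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        combined = np.concatenate([a, b])
        if np.unique(combined).size < 2:
            warnings.warn(f"{var} is constant within the sub-sample; "
                          "treated as balanced")
            pvals[var] = 1.0
            continue
        if var in CONTINUOUS_VARIABLES:
            res = stats.ttest_ind(a, b, equal_var=False)
            p = float(res.pvalue)
            if not np.isfinite(p):   # zero within-group variance
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            levels = np.unique(combined)
            table = np.array([[np.sum(g == lv) for lv in levels]
                              for g in (a, b)])
            table = table[:, table.sum(axis=0) > 0]
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            p = float(p)
        pvals[var] = p
    accept = min(pvals.values()) >= alpha
    return pvals, accept


def build_ensemble(pheno: PhenotypeTable, config: RunConfig,
                   rng: np.random.Generator,
                   variables=DEFAULT_MATCH_VARIABLES) -> SubsampleEnsemble:
    """Rejection-sample balanced sub-samples until ``n_subsamples`` accepted.

    Fails with an acceptance-rate diagnostic when the attempt budget
    (100x the target count) is exhausted — the signature of confounding
    too strong to match away.
    """
    case_ids = np.array(pheno.case_ids)
    control_ids = np.array(pheno.control_ids)
    accepted: list[tuple[np.ndarray, np.ndarray]] = []
    balance: list[dict[str, float]] = []
    budget = ATTEMPT_BUDGET_FACTOR * config.n_subsamples
    attempts = 0
    while len(accepted) < config.n_subsamples:
        if attempts >= budget:
            rate = len(accepted) / attempts
            raise RuntimeError(
                f"sub-sample attempt budget exhausted: {len(accepted)} accepted "
                f"in {attempts} attempts (acceptance rate {rate:.4f}); "
                "confounding may be too strong to balance by rejection")
        sub = draw_subsample(case_ids, control_ids, config.n_cases_sub,
                             config.n_controls_sub, rng)
        attempts += 1
        pvals, ok = balance_check(sub, pheno, variables, config.balance_alpha)
        if ok:
            accepted.append(sub)
            balance.append(pvals)
    return SubsampleEnsemble(accepted, balance, tuple(variables), attempts)


def rdm_scan(matrix: GenotypeMatrix, pheno: PhenotypeTable,
             ensemble: SubsampleEnsemble, config: RunConfig) -> pd.DataFrame:
    """Adjusted per-SNP logistic tests within every accepted sub-sample.

    Within each sub-sample the SNP-level QC (call rate, MAF) is re-applied;
    a SNP failing it there is skipped for that sub-sample (not counted as
    evaluated). Model failures (separation / non-convergence) count as
    non-evaluated, never as significant. Per-SNP ORs are summarized by
    their median and 2.5-97.5 percentile range across sub-samples.
    """
    m = matrix.n_snps
    n_eval = np.zeros(m, dtype=int)
    n_sig = np.zeros(m, dtype=int)
    ors: list[list[float]] = [[] for _ in range(m)]

    for case_ids, control_ids in ensemble.subsamples:
        ids = list(case_ids) + list(control_ids)
        rows = matrix.sample_indices(ids)
        D = matrix.dosages[rows]
        sub_ph = pheno.subset(ids)
        y = sub_ph.y
        covs = sub_ph.covariate_matrix(ADJUST_COVARIATES)

        call = np.isfinite(D).mean(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(D, axis=0) / (2.0 * np.maximum(
                np.isfinite(D).sum(axis=0), 1))
        maf = np.minimum(freq, 1.0 - freq)
        usable = (call >= config.snp_call_min) & (maf >= config.maf_min)
        if not usable.any():
            continue
        fits = fit_logistic_many(D[:, usable], covs, y)
        cols = np.where(usable)[0]
        pv = fits["p"].to_numpy()
        bv = fits["beta"].to_numpy()
        valid = fits["converged"].to_numpy() & ~fits["separated"].to_numpy() \
            & np.isfinite(pv)
        for local, j in enumerate(cols):
            if not valid[local]:
                continue
            n_eval[j] += 1
            if pv[local] < config.test_alpha:
                n_sig[j] += 1
            ors[j].append(float(np.exp(bv[local])))

    with np.errstate(invalid="ignore"):
        frac = np.where(n_eval > 0, n_sig / np.maximum(n_eval, 1), np.nan)
    rows_out = []
    for j, snp in enumerate(matrix.snps):
        arr = np.array(ors[j])
        rows_out.append({
            "snp_id": snp.snp_id,
            "n_evaluated": int(n_eval[j]), "n_significant": int(n_sig[j]),
            "fraction_significant": float(frac[j]) if n_eval[j] else np.nan,
            "keep": bool(n_eval[j] and frac[j] > config.keep_fraction),
            "or_median": float(np.median(arr)) if arr.size else np.nan,
            "or_q025": float(np.percentile(arr, 2.5)) if arr.size else np.nan,
            "or_q975": float(np.percentile(arr, 97.5)) if arr.size else np.nan,
        })
    return pd.DataFrame(rows_out)
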