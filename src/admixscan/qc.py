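"""SNP and sample quality control.

Filter order is fixed: (1) SNP call rate, (2) sample call rate on the
surviving SNPs, (3) MAF on the surviving samples. Hardy-Weinberg exact
p-values are computed in controls on the final set, BH-adjusted, and
reported without gating exclusion.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .containers import GenotypeMatrix, PhenotypeTable
from .io_config import RunConfig


def compute_maf(dosages: np.ndarray, *, return_orientation: bool = False):
    """Minor allele frequency from a dosage vector, missing excluded.

    The coded-allele frequency is folded to <= 0.5; when the coded allele
    turns out to be the common one, the orientation flag is True.
    """
    d = np.asarray(dosages, dtype=float)
    ok = np.isfinite(d)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    freq = d[ok].sum() / (2.0 * n)
    flipped = freq > 0.5
    maf = 1.0 - freq if flipped else freq
    if return_orientation:
        return maf, bool(flipped)
    return maf


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (same parity) whose conditional probability is
    at most that of the observed table. No mid-p correction.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0 or v != int(v):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    # conditional distribution over heterozygote counts k = rare, rare-2, ...
    ks = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - ks) // 2
    hom_common = n - ks - hom_rare
    valid = hom_common >= 0
    ks, hom_rare, hom_common = ks[valid], hom_rare[valid], hom_common[valid]
    logw = (ks * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(ks + 1) - gammaln(hom_common + 1))
    logp = logw - logsumexp(logw)
    p_obs = logp[ks == n_Aa][0]
    # relative tolerance admits exact ties computed in floating point
    pval = float(np.exp(logp)[logp <= p_obs + 1e-10].sum())
    return min(pval, 1.0)


def hwe_from_dosages(dosages: np.ndarray) -> float:
    """HWE exact p for a dosage vector (0/1/2 minor-allele counts)."""
    d = np.asarray(dosages, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return np.nan
    n_aa = int((d == 2).sum())   # minor hom
    n_Aa = int((d == 1).sum())
    n_AA = int((d == 0).sum())
    return hwe_exact_test(n_AA, n_Aa, n_aa)


@dataclass
class QCReport:
    """Per-SNP and per-sample QC metrics plus attrition counts."""

    snp_table: pd.DataFrame      # indexed by snp_id
    sample_table: pd.DataFrame   # indexed by sample_id
    summary: dict


def apply_filters(matrix: GenotypeMatrix, pheno: PhenotypeTable,
                  config: RunConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Run the documented filter cascade and HWE screen.

    Returns the filtered matrix and a report; raises if nothing survives.
    ``config.maf_scope`` selects whether the MAF filter uses the pooled
    sample (default) or controls only.
    """
    from .association import bh_fdr  # local import avoids a cycle

    snp_ids = matrix.snp_ids
    # step 1: SNP call rate on all samples
    snp_cr = matrix.snp_call_rates()
    snp_pass_call = snp_cr >= config.snp_call_min
    step1 = matrix.take_snps(np.where(snp_pass_call)[0])

    # step 2: sample call rate on surviving SNPs
    samp_cr_surv = step1.sample_call_rates() if step1.n_snps else \
        np.ones(matrix.n_samples)
    samp_pass = samp_cr_surv >= config.sample_call_min
    step2 = step1.take_samples(np.where(samp_pass)[0])

    # step 3: MAF on surviving samples
    if config.maf_scope == "controls":
        control_ids = [s for s in step2.samples
                       if pheno.data.loc[s, "status"] == "control"]
        maf_rows = step2.sample_indices(control_ids)
    else:
        maf_rows = np.arange(step2.n_samples)
    mafs_surv = np.array([
        compute_maf(step2.dosages[maf_rows, j])
        if np.isfinite(step2.dosages[maf_rows, j]).any() else 0.0
        for j in range(step2.n_snps)])
    maf_pass = mafs_surv >= config.maf_min
    final = step2.take_snps(np.where(maf_pass)[0])
    if final.n_snps == 0 or final.n_samples == 0:
        raise ValueError(
            "QC removed everything: "
            f"SNP call-rate filter kept {step1.n_snps}/{matrix.n_snps}, "
            f"sample filter kept {step2.n_samples}/{matrix.n_samples}, "
            f"MAF filter kept {final.n_snps}/{step1.n_snps}")

    # HWE in controls on the final set (reported, never excluding)
    control_rows = final.sample_indices(
        [s for s in final.samples if pheno.data.loc[s, "status"] == "control"])
    hwe_p = np.array([hwe_from_dosages(final.dosages[control_rows, j])
                      for j in range(final.n_snps)])
    hwe_q = bh_fdr(hwe_p)

    # assemble per-SNP report aligned to the input SNP order
    snp_tab = pd.DataFrame(index=pd.Index(snp_ids, name="snp_id"))
    snp_tab["call_rate"] = snp_cr
    snp_tab["pass_call_rate"] = snp_pass_call
    maf_all = pd.Series(np.nan, index=snp_tab.index)
    maf_all.loc[step2.snp_ids] = mafs_surv
    snp_tab["maf"] = maf_all
    passed_maf = pd.Series(False, index=snp_tab.index)
    passed_maf.loc[step2.snp_ids] = maf_pass
    snp_tab["pass_maf"] = passed_maf
    snp_tab["pass"] = snp_tab["pass_call_rate"] & snp_tab["pass_maf"]
    hwe_col = pd.Series(np.nan, index=snp_tab.index)
    hwe_col.loc[final.snp_ids] = hwe_p
    snp_tab["hwe_p_controls"] = hwe_col
    hweq_col = pd.Series(np.nan, index=snp_tab.index)
    hweq_col.loc[final.snp_ids] = hwe_q
    snp_tab["hwe_q_controls"] = hweq_col

    samp_tab = pd.DataFrame(index=pd.Index(matrix.samples, name="sample_id"))
    cr_col = pd.Series(np.nan, index=samp_tab.index)
    cr_col.loc[step1.samples] = samp_cr_surv
    samp_tab["call_rate"] = cr_col
    pass_col = pd.Series(False, index=samp_tab.index)
    pass_col.loc[step1.samples] = samp_pass
    samp_tab["pass"] = pass_col

    summary = {
        "snps_in": matrix.n_snps, "snps_out": final.n_snps,
        "samples_in": matrix.n_samples, "samples_out": final.n_samples,
        "snps_fail_call_rate": int((~snp_pass_call).sum()),
        "samples_fail_call_rate": int((~samp_pass).sum()),
        "snps_fail_maf": int((~maf_pass).sum()),
    }
    return final, QCReport(snp_tab, samp_tab, summary)
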