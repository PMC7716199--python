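"""Haplotype-level analysis: pairwise LD, EM frequency estimation from
unphased genotypes, and per-haplotype association testing.

Phase is never observed. For a set of k SNPs (2 <= k <= 6) each individual
with h heterozygous sites is compatible with 2^(h-1) unordered diplotypes;
the EM algorithm iterates between posterior diplotype weights proportional
to f(h1)f(h2) (doubled for h1 != h2, i.e. haplotype-level Hardy-Weinberg)
and frequency re-estimation from expected haplotype counts. Association
uses the posterior-mean haplotype dosage (0-2) as the predictor so phase
uncertainty propagates into the test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import ADJUST_COVARIATES, bh_fdr, fit_logistic
from .containers import GenotypeMatrix, PhenotypeTable, SNPInfo
from .io_config import RunConfig


# ---------------------------------------------------------------------------
# Diplotype enumeration
# ---------------------------------------------------------------------------

def _compatible_pairs(g: np.ndarray) -> list[tuple[int, int]]:
    """Unordered haplotype pairs (as bitmasks, bit j = minor at SNP j)
    compatible with one complete genotype vector over k SNPs."""
    k = g.size
    base = 0
    for j in range(k):
        if g[j] == 2:
            base |= 1 << j
    het = [j for j in range(k) if g[j] == 1]
    if not het:
        return [(base, base)]
    pairs = []
    first, rest = het[0], het[1:]
    for bits in range(1 << len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for i, j in enumerate(rest):
            if bits >> i & 1:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2))
    return pairs


def _hap_string(mask: int, snps: list[SNPInfo] | None, k: int) -> str:
    if snps is None:
        return "".join("1" if mask >> j & 1 else "0" for j in range(k))
    return "".join(s.allele_minor if mask >> j & 1 else s.allele_major
                   for j, s in enumerate(snps))


# ---------------------------------------------------------------------------
# EM core
# ---------------------------------------------------------------------------

def _em_core(pair_lists: list[list[tuple[int, int]]], hap_of: dict[int, int],
             n_hap: int, tol: float, max_iter: int
             ) -> tuple[np.ndarray, list[float], bool]:
    """EM over haplotype frequencies. Returns (freqs, loglik trace, converged)."""
    n = len(pair_lists)
    h1 = np.array([hap_of[a] for pl in pair_lists for a, _ in pl])
    h2 = np.array([hap_of[b] for pl in pair_lists for _, b in pl])
    indiv = np.repeat(np.arange(n), [len(pl) for pl in pair_lists])
    mult = np.where(h1 == h2, 1.0, 2.0)

    # init: uniform over haplotypes compatible with this dataset
    seen = np.zeros(n_hap, dtype=bool)
    seen[h1] = True
    seen[h2] = True
    f = seen / seen.sum()
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        wgt = mult * f[h1] * f[h2]
        denom = np.bincount(indiv, weights=wgt, minlength=n)
        safe = np.where(denom > 0, denom, 1.0)
        post = wgt / safe[indiv]
        # individuals with vanished support fall back to uniform over pairs
        dead = denom <= 0
        if dead.any():
            counts_per = np.bincount(indiv, minlength=n)
            post[dead[indiv]] = 1.0 / counts_per[indiv][dead[indiv]]
        trace.append(float(np.log(safe).sum()))
        counts = (np.bincount(h1, weights=post, minlength=n_hap)
                  + np.bincount(h2, weights=post, minlength=n_hap))
        f_new = counts / (2.0 * n)
        if np.abs(f_new - f).max() < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return f, trace, converged


@dataclass
class HaplotypeSet:
    """EM output for one SNP set: frequencies per group, posterior-mean
    haplotype dosages for the complete-genotype individuals."""

    snp_ids: list[str]
    haplotypes: list[str]
    freq_pooled: np.ndarray
    freq_cases: np.ndarray
    freq_controls: np.ndarray
    dosages: np.ndarray          # (n_complete, n_hap) expected counts, sum 2
    sample_ids: list[str]        # complete-genotype individuals, row order
    loglik_trace: list[float]
    n_iterations: int
    converged: bool


def em_haplotypes(matrix: GenotypeMatrix, snp_ids: list[str],
                  pheno: PhenotypeTable | None = None,
                  config: RunConfig | None = None) -> HaplotypeSet:
    """Estimate haplotype frequencies over a set of 2-6 SNPs.

    Individuals with any missing genotype among the SNPs are excluded.
    Frequencies are estimated pooled and, when a phenotype table is given,
    separately in cases and controls; expected dosages always come from the
    pooled (phenotype-blind) fit.
    """
    config = config or RunConfig()
    k = len(snp_ids)
    if not (2 <= k <= 6):
        raise ValueError("haplotype sets must span 2 to 6 SNPs")
    idx = [matrix.snp_index(s) for s in snp_ids]
    sub = matrix.dosages[:, idx]
    complete = np.isfinite(sub).all(axis=1)
    if complete.sum() == 0:
        raise ValueError("no individuals with complete genotypes for this SNP set")
    G = sub[complete].astype(int)
    sample_ids = [matrix.samples[i] for i in np.where(complete)[0]]
    snps = [matrix.snps[i] for i in idx]

    pair_lists = [_compatible_pairs(g) for g in G]
    universe = sorted({h for pl in pair_lists for pr in pl for h in pr})
    hap_of = {h: i for i, h in enumerate(universe)}
    n_hap = len(universe)

    f_pool, trace, conv = _em_core(pair_lists, hap_of, n_hap,
                                   config.em_tol, config.em_max_iter)

    # posterior-mean dosages under the pooled frequencies
    dos = np.zeros((len(pair_lists), n_hap))
    for i, pl in enumerate(pair_lists):
        w = np.array([(1.0 if a == b else 2.0) * f_pool[hap_of[a]] * f_pool[hap_of[b]]
                      for a, b in pl])
        tot = w.sum()
        w = w / tot if tot > 0 else np.full(len(pl), 1.0 / len(pl))
        for (a, b), wi in zip(pl, w):
            dos[i, hap_of[a]] += wi
            dos[i, hap_of[b]] += wi

    f_cases = np.full(n_hap, np.nan)
    f_controls = np.full(n_hap, np.nan)
    if pheno is not None:
        status = pheno.data["status"].reindex(sample_ids)
        for label, out in (("case", f_cases), ("control", f_controls)):
            rows = np.where((status == label).to_numpy())[0]
            if rows.size:
                fg, _, _ = _em_core([pair_lists[i] for i in rows], hap_of,
                                    n_hap, config.em_tol, config.em_max_iter)
                out[:] = fg

    return HaplotypeSet(
        snp_ids=list(snp_ids),
        haplotypes=[_hap_string(h, snps, k) for h in universe],
        freq_pooled=f_pool, freq_cases=f_cases, freq_controls=f_controls,
        dosages=dos, sample_ids=sample_ids,
        loglik_trace=trace, n_iterations=len(trace), converged=conv)


# ---------------------------------------------------------------------------
# Pairwise LD
# ---------------------------------------------------------------------------

def ld_pair(dos_a: np.ndarray, dos_b: np.ndarray
            ) -> tuple[float, float, float, float]:
    """LD between two SNPs from EM-estimated two-locus haplotype frequencies.

    Returns (D, D', r^2, p) with p from chi2 = 2n r^2 on 1 df, n the number
    of complete-genotype individuals.
    """
    a = np.asarray(dos_a, dtype=float)
    b = np.asarray(dos_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        raise ValueError("no shared non-missing genotypes")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("LD undefined: a SNP is monomorphic on the shared samples")
    G = np.column_stack([a, b]).astype(int)
    pair_lists = [_compatible_pairs(g) for g in G]
    universe = sorted({h for pl in pair_lists for pr in pl for h in pr})
    hap_of = {h: i for i, h in enumerate(universe)}
    f, _, _ = _em_core(pair_lists, hap_of, len(universe), 1e-10, 2000)

    def freq(mask: int) -> float:
        return float(f[hap_of[mask]]) if mask in hap_of else 0.0

    p_ab = freq(0b11)                       # minor at both
    p_a = p_ab + freq(0b01)                 # minor at SNP A (bit 0)
    p_b = p_ab + freq(0b10)
    D = p_ab - p_a * p_b
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = D * D / denom if denom > 0 else 0.0
    chi2 = 2.0 * n * r2
    p = float(stats.chi2.sf(chi2, df=1))
    return float(D), float(min(dprime, 1.0)), float(min(r2, 1.0)), p


def ld_matrix(matrix: GenotypeMatrix, snp_ids: list[str]) -> pd.DataFrame:
    """All pairwise LD statistics for a SNP list (long format)."""
    rows = []
    for sa, sb in combinations(snp_ids, 2):
        da = matrix.dosages[:, matrix.snp_index(sa)]
        db = matrix.dosages[:, matrix.snp_index(sb)]
        try:
            D, dp, r2, p = ld_pair(da, db)
            rows.append({"snp_a": sa, "snp_b": sb, "D": D, "Dprime": dp,
                         "r2": r2, "p": p})
        except ValueError:
            rows.append({"snp_a": sa, "snp_b": sb, "D": np.nan,
                         "Dprime": np.nan, "r2": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def significant_ld_groups(matrix: GenotypeMatrix, gene_of_snp: dict[str, str],
                          config: RunConfig | None = None) -> dict[str, list[str]]:
    """Per gene, the SNPs participating in at least one significant LD pair
    (pairwise chi-square p, BH-adjusted within the gene, below ld_alpha).
    Genes retaining fewer than two SNPs are dropped."""
    config = config or RunConfig()
    genes: dict[str, list[str]] = {}
    for snp, gene in gene_of_snp.items():
        genes.setdefault(gene, []).append(snp)
    out: dict[str, list[str]] = {}
    for gene, snps in genes.items():
        snps = [s for s in snps if s in matrix.snp_ids]
        if len(snps) < 2:
            continue
        tab = ld_matrix(matrix, snps)
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        sig = tab[tab["q"] < config.ld_alpha]
        members = sorted(set(sig["snp_a"]) | set(sig["snp_b"]),
                         key=lambda s: matrix.snp_index(s))
        if len(members) >= 2:
            out[gene] = members
    return out


# ---------------------------------------------------------------------------
# Haplotype association
# ---------------------------------------------------------------------------

def haplotype_association(hapset: HaplotypeSet, pheno: PhenotypeTable,
                          config: RunConfig | None = None) -> pd.DataFrame:
    """One-vs-rest adjusted logistic test per haplotype.

    Predictor is the posterior-mean dosage from the pooled EM; haplotypes
    with pooled frequency below ``rare_hap_pool_freq`` are pooled into a
    single "rare" unit; q-values are BH within the set.
    """
    config = config or RunConfig()
    sub = pheno.subset(hapset.sample_ids)
    y = sub.y
    covs = sub.covariate_matrix(ADJUST_COVARIATES)

    common = hapset.freq_pooled >= config.rare_hap_pool_freq
    if not common.any():
        raise ValueError("all haplotypes below the rare-frequency threshold")
    units: list[tuple[str, np.ndarray, float, float, float]] = []
    for i in np.where(common)[0]:
        units.append((hapset.haplotypes[i], hapset.dosages[:, i],
                      hapset.freq_pooled[i], hapset.freq_cases[i],
                      hapset.freq_controls[i]))
    if (~common).any():
        units.append(("rare", hapset.dosages[:, ~common].sum(axis=1),
                      float(hapset.freq_pooled[~common].sum()),
                      float(np.nansum(hapset.freq_cases[~common])),
                      float(np.nansum(hapset.freq_controls[~common]))))

    rows = []
    for name, dose, fp, fc_case, fc_ctrl in units:
        rec = {"haplotype": name, "freq_pooled": fp,
               "freq_cases": fc_case, "freq_controls": fc_ctrl}
        try:
            fit = fit_logistic(dose, covs, y)
            rec.update(beta=fit.beta, se=fit.se, p=fit.p,
                       or_adj=float(np.exp(fit.beta)),
                       ci95_low=float(np.exp(fit.beta - 1.96 * fit.se)),
                       ci95_high=float(np.exp(fit.beta + 1.96 * fit.se)),
                       n_used=fit.n_used, separated=fit.separated)
        except ValueError as exc:
            rec.update(beta=np.nan, se=np.nan, p=np.nan, or_adj=np.nan,
                       ci95_low=np.nan, ci95_high=np.nan, n_used=0,
                       separated=False, note=str(exc))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


def haplotype_rdm(matrix: GenotypeMatrix, snp_ids: list[str],
                  pheno: PhenotypeTable, ensemble,
                  config: RunConfig | None = None) -> pd.DataFrame:
    """Randomized sub-sampling analysis at the haplotype level.

    The EM is re-run within each sub-sample (pooled, phenotype-blind);
    each sufficiently frequent haplotype is tested one-vs-rest with the
    adjusted logistic model; haplotypes are matched across sub-samples by
    allele string and aggregated exactly as in the SNP-level procedure.
    """
    config = config or RunConfig()
    stats_by_hap: dict[str, dict] = {}
    for case_ids, control_ids in ensemble.subsamples:
        ids = list(case_ids) + list(control_ids)
        rows = matrix.sample_indices(ids)
        sub_matrix = matrix.take_samples(rows)
        try:
            hapset = em_haplotypes(sub_matrix, snp_ids,
                                   pheno.subset(ids), config)
            tab = haplotype_association(hapset, pheno.subset(hapset.sample_ids),
                                        config)
        except ValueError:
            continue
        for _, row in tab.iterrows():
            name = row["haplotype"]
            if name == "rare":
                continue
            rec = stats_by_hap.setdefault(
                name, {"n_evaluated": 0, "n_significant": 0, "ors": []})
            if not np.isfinite(row["p"]):
                continue
            rec["n_evaluated"] += 1
            if row["p"] < config.test_alpha:
                rec["n_significant"] += 1
            rec["ors"].append(row["or_adj"])
    out_rows = []
    for name, rec in stats_by_hap.items():
        ne, ns = rec["n_evaluated"], rec["n_significant"]
        frac = ns / ne if ne else np.nan
        ors = np.array(rec["ors"])
        out_rows.append({
            "haplotype": name, "n_evaluated": ne, "n_significant": ns,
            "fraction_significant": frac,
            "keep": bool(ne and frac > config.keep_fraction),
            "or_median": float(np.median(ors)) if ors.size else np.nan,
            "or_q025": float(np.percentile(ors, 2.5)) if ors.size else np.nan,
            "or_q975": float(np.percentile(ors, 97.5)) if ors.size else np.nan,
        })
    return pd.DataFrame(out_rows)
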