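"""Synthetic admixed case-control data generator.

Emulates the kind of cohort the pipeline is built for: a three-way admixed
population (European / African / Native American, predominantly European),
candidate SNPs with Balding-Nichols population differentiation, small LD
blocks of 2-4 SNPs, ancestry-correlated confounders (SES, education, BMI,
age), planted additive SNP and haplotype effects, per-entry missingness,
and the case/control confounder imbalance the randomized sub-sampling
procedure is meant to neutralize.

Sampling is retrospective: a population stream is generated with a
marginal case rate of about 10% (the intercept is solved numerically) and
individuals are enrolled until the requested case and control counts are
reached, keeping the odds ratio the natural estimand.

Determinism: one RNG stream per logical stage (ancestral frequencies,
block haplotype frequencies, ancestry, gametes, covariates, status,
missingness, allele letters), all derived from the master seed, so a
given seed reproduces the emitted files bitwise.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .containers import GenotypeMatrix, PhenotypeTable, SNPInfo, VALID_BASES

POPULATIONS = ("EUR", "AFR", "NAT")
TARGET_CASE_RATE = 0.10
POOL_BUDGET_FACTOR = 100

_STAGES = ("freqs", "hapfreqs", "ancestry", "gametes", "covariates",
           "status", "missingness", "alleles")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class LDBlock:
    """A small LD block: consecutive SNP indices sharing drawn haplotypes.

    ``base_freqs`` are the ancestral frequencies of the 2^k haplotypes
    (bit j of the haplotype index = minor allele at the j-th block SNP);
    population-specific frequencies are drawn around them with a
    Dirichlet of concentration (1-F)/F * base on the haplotype simplex.
    """

    snp_indices: tuple[int, ...]
    base_freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.snp_indices)
        if not (2 <= k <= 4):
            raise ValueError("LD blocks span 2-4 SNPs")
        if len(self.base_freqs) != 2 ** k:
            raise ValueError(f"block over {k} SNPs needs {2**k} haplotype "
                             f"frequencies, got {len(self.base_freqs)}")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("block haplotype frequencies must sum to 1")


@dataclass
class EffectSpec:
    """A planted effect: additive on the log-odds of disease.

    ``kind`` is "snp" (target = SNP index) or "haplotype" (target =
    (block index, haplotype index)); ``log_or`` the per-copy log odds
    ratio.
    """

    kind: str
    target: object
    log_or: float

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "haplotype"):
            raise ValueError("effect kind must be 'snp' or 'haplotype'")


@dataclass
class ConfounderModel:
    """Ancestry -> covariate links.

    SES and education are 3-level ordinals from a latent Gaussian loading
    on European ancestry (higher ancestry, higher level); BMI is Gaussian
    with a shift proportional to the non-European fraction; age is a
    truncated Gaussian bounded below at the cohort entry age.
    """

    ses_loading: float = 1.5
    ses_thresholds: tuple[float, float] = (-0.5, 0.8)
    edu_loading: float = 1.2
    edu_thresholds: tuple[float, float] = (-0.5, 0.8)
    bmi_intercept: float = 26.0
    bmi_nonEur_beta: float = 2.0
    bmi_sd: float = 4.0
    age_mean: float = 60.0
    age_sd: float = 8.0
    age_min: float = 45.0


@dataclass
class SimulationConfig:
    """Every generator knob, with study-scale defaults.

    Defaults: 176 cases / 183 controls; 141 SNPs with base MAF in
    (0.05, 0.5); Dirichlet(8, 1, 1) ancestry (mean 80% European);
    FST 0.1; four LD blocks; planted SNP odds ratios spanning the
    moderate-risk range plus one protective variant and one haplotype
    risk effect; SES/education/age imbalance between cases and controls.
    """

    n_cases: int = 176
    n_controls: int = 183
    n_snps: int = 141
    dirichlet_alpha: tuple[float, float, float] = (8.0, 1.0, 1.0)
    fst: float = 0.1
    base_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: list[LDBlock] = field(default_factory=lambda: [
        # 2-SNP blocks with strong LD plus one 3-SNP block
        LDBlock((10, 11), (0.45, 0.12, 0.08, 0.35)),
        LDBlock((40, 41), (0.55, 0.05, 0.10, 0.30)),
        LDBlock((80, 81), (0.40, 0.15, 0.15, 0.30)),
        LDBlock((120, 121, 122), (0.30, 0.10, 0.05, 0.10,
                                  0.05, 0.10, 0.10, 0.20)),
    ])
    effects: list[EffectSpec] = field(default_factory=lambda: [
        EffectSpec("snp", 5, float(np.log(1.62))),
        EffectSpec("snp", 25, float(np.log(1.45))),
        EffectSpec("snp", 60, float(np.log(1.88))),
        EffectSpec("snp", 100, float(np.log(0.48))),
        EffectSpec("haplotype", (1, 3), float(np.log(1.75))),
    ])
    confounder_model: ConfounderModel = field(default_factory=ConfounderModel)
    # log-ORs of (centered) SES, education and age on case status: strong
    # enough that the realized SES x status table is usually significant at
    # cohort scale, weak enough that rejection matching stays feasible
    confounder_status_bias: dict = field(default_factory=lambda: {
        "ses": 0.35, "education": 0.20, "age": 0.02})
    missing_rate_snp: float = 0.02
    missing_rate_sample: float = 0.0
    highmiss_snps: tuple[int, ...] = ()
    highmiss_snp_rate: float = 0.15
    lowcall_samples: int = 0
    lowcall_sample_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must be positive elementwise")
        lo, hi = self.base_maf_range
        if not (0.01 < lo < hi <= 0.5):
            raise ValueError("base_maf_range must be an interval within (0.01, 0.5]")
        block_snps = [j for b in self.ld_blocks for j in b.snp_indices]
        if len(set(block_snps)) != len(block_snps):
            raise ValueError("LD blocks overlap")
        if any(j >= self.n_snps for j in block_snps):
            raise ValueError("LD block SNP index out of range")
        for e in self.effects:
            if e.kind == "snp":
                if not (0 <= e.target < self.n_snps):
                    raise ValueError(f"effect SNP index {e.target} out of range")
            else:
                bi, hi_ = e.target
                if not (0 <= bi < len(self.ld_blocks)):
                    raise ValueError(f"effect block index {bi} out of range")
                if not (0 <= hi_ < len(self.ld_blocks[bi].base_freqs)):
                    raise ValueError(f"effect haplotype index {hi_} out of range")
        for r in (self.missing_rate_snp, self.missing_rate_sample,
                  self.highmiss_snp_rate, self.lowcall_sample_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("missingness rates must lie in [0, 1)")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One independent RNG stream per generator stage."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STAGES, children)}


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Everything the generator knows that an analyst would not."""

    ancestry: np.ndarray            # (n_samples, 3) true proportions
    pop_freqs: np.ndarray           # (3, n_snps) minor-allele frequencies
    effects: list[EffectSpec]
    block_haplotypes: dict[int, np.ndarray]  # block idx -> (n, 2) gamete haps
    block_pop_freqs: dict[int, np.ndarray]   # block idx -> (3, 2^k)
    intercept: float
    sample_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "ancestry": self.ancestry.tolist(),
            "pop_freqs": self.pop_freqs.tolist(),
            "effects": [asdict(e) for e in self.effects],
            "block_haplotypes": {str(k): v.tolist()
                                 for k, v in self.block_haplotypes.items()},
            "block_pop_freqs": {str(k): v.tolist()
                                for k, v in self.block_pop_freqs.items()},
            "intercept": self.intercept,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def sample_ancestral_freqs(n_snps: int, fst: float,
                           base_maf_range: tuple[float, float],
                           rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols population frequencies.

    For each SNP an ancestral frequency p ~ U(base_maf_range); each
    population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F), clipped to
    [0.01, 0.99]. Returns shape (3, n_snps).
    """
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie in (0, 1)")
    lo, hi = base_maf_range
    p = rng.uniform(lo, hi, size=n_snps)
    c = (1.0 - fst) / fst
    freqs = rng.beta(np.broadcast_to(p * c, (len(POPULATIONS), n_snps)),
                     np.broadcast_to((1.0 - p) * c, (len(POPULATIONS), n_snps)))
    return np.clip(freqs, 0.01, 0.99)


def sample_block_pop_freqs(block: LDBlock, fst: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Population haplotype frequencies for one LD block: Dirichlet with
    concentration (1-F)/F * base frequencies on the haplotype simplex."""
    c = (1.0 - fst) / fst
    alpha = np.asarray(block.base_freqs) * c
    out = rng.dirichlet(alpha, size=len(POPULATIONS))
    out = np.clip(out, 1e-6, None)
    return out / out.sum(axis=1, keepdims=True)


def sample_ancestry(n: int, dirichlet_alpha, rng: np.random.Generator
                    ) -> np.ndarray:
    return rng.dirichlet(np.asarray(dirichlet_alpha, dtype=float), size=n)


def simulate_genotypes(ancestry: np.ndarray, pop_freqs: np.ndarray,
                       ld_blocks: Sequence[LDBlock],
                       block_pop_freqs: Sequence[np.ndarray],
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Draw unphased dosages for a batch of individuals.

    Independent SNPs: each gamete carries the minor allele with
    probability q_i = sum_k anc_k * freq_k. LD-block SNPs: each gamete
    draws a whole haplotype from the individual's ancestry-mixed block
    haplotype distribution. Returns (dosages, block gamete haplotypes).
    """
    n, _ = ancestry.shape
    m = pop_freqs.shape[1]
    if not np.allclose(ancestry.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("ancestry proportions must sum to 1")
    q = ancestry @ pop_freqs                       # (n, m)
    dosages = rng.binomial(1, q).astype(float) + rng.binomial(1, q)
    block_haps: dict[int, np.ndarray] = {}
    for bi, (block, popf) in enumerate(zip(ld_blocks, block_pop_freqs)):
        if not np.allclose(popf.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("block haplotype frequencies must sum to 1")
        probs = ancestry @ popf                    # (n, 2^k)
        cum = probs.cumsum(axis=1)
        cum /= cum[:, -1:]
        u = rng.random((n, 2))
        haps = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # (n, 2)
        block_haps[bi] = haps
        for j, snp_idx in enumerate(block.snp_indices):
            dosages[:, snp_idx] = ((haps >> j) & 1).sum(axis=1)
    return dosages, block_haps


def assign_covariates(ancestry: np.ndarray, model: ConfounderModel,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw SES, education, BMI and age given ancestry."""
    n = ancestry.shape[0]
    anc_eur = ancestry[:, 0]
    # latent loadings act on the deviation from the typical European
    # fraction so batch composition cannot leak into the thresholds
    anc_eur_c = anc_eur - 0.8

    def ordinal(loading: float, thresholds: tuple[float, float]) -> np.ndarray:
        latent = loading * anc_eur_c + rng.standard_normal(n)
        return 1 + (latent > thresholds[0]).astype(int) \
                 + (latent > thresholds[1]).astype(int)

    ses = ordinal(model.ses_loading, model.ses_thresholds)
    edu = ordinal(model.edu_loading, model.edu_thresholds)
    bmi = model.bmi_intercept + model.bmi_nonEur_beta * (1.0 - anc_eur) \
        + model.bmi_sd * rng.standard_normal(n)
    a = (model.age_min - model.age_mean) / model.age_sd
    age = truncnorm.rvs(a, np.inf, loc=model.age_mean, scale=model.age_sd,
                        size=n, random_state=rng)
    return pd.DataFrame({"age": age, "bmi": bmi, "ses": ses, "education": edu})


def _genetic_score(dosages: np.ndarray, block_haps: dict[int, np.ndarray],
                   effects: Sequence[EffectSpec]) -> np.ndarray:
    score = np.zeros(dosages.shape[0])
    for e in effects:
        if e.kind == "snp":
            score += e.log_or * dosages[:, e.target]
        else:
            bi, hi = e.target
            score += e.log_or * (block_haps[bi] == hi).sum(axis=1)
    return score


def _confounder_score(covs: pd.DataFrame, bias: dict,
                      model: ConfounderModel) -> np.ndarray:
    return (bias.get("ses", 0.0) * (covs["ses"].to_numpy() - 2.0)
            + bias.get("education", 0.0) * (covs["education"].to_numpy() - 2.0)
            + bias.get("age", 0.0) * (covs["age"].to_numpy() - model.age_mean))


def solve_intercept(linear: np.ndarray,
                    target_rate: float = TARGET_CASE_RATE) -> float:
    """Intercept b0 with mean(expit(b0 + linear)) = target_rate."""
    def gap(b0: float) -> float:
        return float(expit(b0 + linear).mean() - target_rate)
    lo, hi = -30.0, 30.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_phenotypes(dosages: np.ndarray, block_haps: dict[int, np.ndarray],
                        covariates: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator,
                        intercept: Optional[float] = None
                        ) -> tuple[np.ndarray, float]:
    """Case indicators for a population batch.

    Case probability = expit(b0 + genetic score + confounder score); b0 is
    solved on the batch for a ~10% population case rate unless supplied.
    """
    linear = _genetic_score(dosages, block_haps, config.effects) \
        + _confounder_score(covariates, config.confounder_status_bias,
                            config.confounder_model)
    if intercept is None:
        intercept = solve_intercept(linear)
    prob = expit(intercept + linear)
    return rng.binomial(1, prob).astype(int), float(intercept)


def inject_missingness(dosages: np.ndarray, config: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Set entries missing independently; designated SNPs / leading samples
    can carry elevated rates to guarantee QC casualties."""
    out = dosages.astype(float).copy()
    n, m = out.shape
    rate = np.full(m, config.missing_rate_snp)
    if config.highmiss_snps:
        rate[list(config.highmiss_snps)] = config.highmiss_snp_rate
    mask = rng.random((n, m)) < rate[None, :]
    if config.missing_rate_sample > 0:
        mask |= rng.random((n, m)) < config.missing_rate_sample
    if config.lowcall_samples > 0:
        mask[:config.lowcall_samples] |= (
            rng.random((config.lowcall_samples, m)) < config.lowcall_sample_rate)
    out[mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _snp_metadata(n_snps: int, rng: np.random.Generator) -> list[SNPInfo]:
    """Invented but deterministic SNP identities: spread over chromosomes
    1-22 with random distinct allele letters."""
    snps = []
    for j in range(n_snps):
        chrom = str(j % 22 + 1)
        pos = 1_000_000 + 10_000 * (j // 22 + 1) + j
        minor, major = rng.choice(list(VALID_BASES), size=2, replace=False)
        snps.append(SNPInfo(f"snp{j:04d}", chrom, pos, str(minor), str(major)))
    return snps


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Generate one complete case-control dataset plus its truth record.

    A population pool is streamed (in one vectorized draw, topped up if
    needed) and individuals are enrolled in stream order until the case
    and control quotas are filled; the total stream is capped at 100x the
    requested cohort size.
    """
    rngs = stage_rngs(config.seed)
    pop_freqs = sample_ancestral_freqs(config.n_snps, config.fst,
                                       config.base_maf_range, rngs["freqs"])
    block_popfreqs = [sample_block_pop_freqs(b, config.fst, rngs["hapfreqs"])
                      for b in config.ld_blocks]

    total = config.n_cases + config.n_controls
    budget = POOL_BUDGET_FACTOR * total
    # expected stream length to fill the case quota at a ~10% case rate
    chunk = min(budget, int(np.ceil(config.n_cases / TARGET_CASE_RATE * 1.4
                                    + config.n_controls)))
    sel_anc, sel_dos, sel_cov, sel_status = [], [], [], []
    sel_haps: dict[int, list[np.ndarray]] = {bi: [] for bi in
                                             range(len(config.ld_blocks))}
    need_cases, need_controls = config.n_cases, config.n_controls
    drawn = 0
    intercept: Optional[float] = None
    while (need_cases > 0 or need_controls > 0):
        if drawn >= budget:
            raise RuntimeError(
                f"could not reach {config.n_cases} cases / "
                f"{config.n_controls} controls within {budget} population "
                f"draws ({need_cases} cases, {need_controls} controls short); "
                "check effect sizes and the confounder bias")
        size = min(chunk, budget - drawn)
        drawn += size
        anc = sample_ancestry(size, config.dirichlet_alpha, rngs["ancestry"])
        dos, bh = simulate_genotypes(anc, pop_freqs, config.ld_blocks,
                                     block_popfreqs, rngs["gametes"])
        cov = assign_covariates(anc, config.confounder_model, rngs["covariates"])
        status, intercept = simulate_phenotypes(dos, bh, cov, config,
                                                rngs["status"], intercept)
        for i in range(size):
            if status[i] == 1 and need_cases > 0:
                need_cases -= 1
            elif status[i] == 0 and need_controls > 0:
                need_controls -= 1
            else:
                continue
            sel_anc.append(anc[i])
            sel_dos.append(dos[i])
            sel_cov.append(cov.iloc[i])
            sel_status.append(status[i])
            for bi in sel_haps:
                sel_haps[bi].append(bh[bi][i])

    ancestry = np.array(sel_anc)
    dosages = np.array(sel_dos)
    status = np.array(sel_status)
    covs = pd.DataFrame(sel_cov).reset_index(drop=True)
    sample_ids = [f"S{i:04d}" for i in range(total)]

    dosages = inject_missingness(dosages, config, rngs["missingness"])
    snps = _snp_metadata(config.n_snps, rngs["alleles"])
    matrix = GenotypeMatrix(sample_ids, snps, dosages)

    pheno = pd.DataFrame({
        "status": np.where(status == 1, "case", "control"),
        "age": covs["age"].to_numpy(),
        "bmi": covs["bmi"].to_numpy(),
        "anc_eur": ancestry[:, 0],
        "anc_afr": ancestry[:, 1],
        "anc_nat": ancestry[:, 2],
        "ses": covs["ses"].to_numpy(),
        "education": covs["education"].to_numpy(),
    }, index=pd.Index(sample_ids, name="sample_id"))
    # guard against float round-off in the simplex
    pheno[["anc_eur", "anc_afr", "anc_nat"]] = (
        pheno[["anc_eur", "anc_afr", "anc_nat"]].div(
            pheno[["anc_eur", "anc_afr", "anc_nat"]].sum(axis=1), axis=0))

    truth = TruthRecord(
        ancestry=ancestry, pop_freqs=pop_freqs, effects=list(config.effects),
        block_haplotypes={bi: np.array(v) for bi, v in sel_haps.items()},
        block_pop_freqs={bi: f for bi, f in enumerate(block_popfreqs)},
        intercept=float(intercept), sample_ids=sample_ids)
    return matrix, PhenotypeTable(pheno), truth


def null_config(n_cases: int = 176, n_controls: int = 183, n_snps: int = 50,
                confounded: bool = True, seed: int = 0) -> SimulationConfig:
    """A no-genetic-effect configuration (optionally keeping the SES /
    education / age imbalance) used for type-I-error studies."""
    bias = {"ses": 0.35, "education": 0.20, "age": 0.02} if confounded \
        else {"ses": 0.0, "education": 0.0, "age": 0.0}
    return SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, n_snps=n_snps,
        ld_blocks=[], effects=[], confounder_status_bias=bias, seed=seed)
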