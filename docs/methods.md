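# Methods

## The analysis design

The package models a small candidate-gene case-control study in a
three-way admixed population. Unphased diploid genotypes over ~100–200
SNPs are coded as minor-allele dosages; per-sample covariates are age,
BMI, individual ancestry proportions (European/African/Native American),
and two 3-level ordinals, socioeconomic status (SES) and education. The
pipeline runs in five stages: quality control, per-SNP association,
randomized matched sub-sampling (RDM), haplotype analysis, and
structure/power diagnostics.

### Quality control

Filter order is fixed and documented because attrition counts depend on
it: (1) drop SNPs with call rate < 90%; (2) drop samples with call rate
< 90% computed on the surviving SNPs; (3) drop SNPs with MAF < 1% on the
surviving samples (pooled by default; a `maf_scope="controls"` option
restricts the frequency estimate to controls). Hardy–Weinberg equilibrium
is then tested in controls on the final set with the exact conditional
test (full enumeration of heterozygote counts at fixed allele counts,
no mid-p), BH-adjusted, and *reported only* — HWE never gates exclusion,
mirroring the common situation in which all surviving markers pass after
FDR correction. The exact test is used instead of the chi-square because
the control groups of interest are small (~160) and alleles can be rare.

### Per-SNP association

The allelic test is a Pearson chi-square on the 2×2 allele-count table
(1 df, no continuity correction); the allelic OR applies the
Haldane–Anscombe +0.5 to all cells iff any cell is zero. The adjusted
analysis is an additive logistic model with covariates age, BMI and the
European ancestry proportion. One ancestry proportion is used because
the three proportions are collinear on the simplex; European fraction is
the natural choice in a predominantly European cohort. Complete-case
handling is per SNP. Note the allelic test is slightly anti-conservative
under admixture (Wahlund excess homozygosity inflates the allele-count
variance; the suite measures ~7% rejection at nominal 5% under the
structured null), which is precisely why the ancestry-adjusted model is
the primary analysis — it holds its level (~5%) in the same simulations.

IRLS fitting: Newton steps with step-halving, convergence when the
maximum absolute score < 1e-8 or the relative log-likelihood change
< 1e-10, at most 50 iterations; standard errors from the inverse observed
information. (Quasi-)separation is flagged — any coefficient beyond ±15
yields `separated=True` and p = NaN — never penalized and never a crash,
matching the behaviour of the genetics tooling of the study's era. A
batched implementation fits one model per SNP simultaneously (shared
covariates; per-SNP dosage column and missingness expressed as
observation weights) and is verified against the scalar fitter to 1e-8;
it is what makes the resampling analyses cheap. FDR is Benjamini–Hochberg
step-up with NaNs excluded from the number of tests.

### Randomized matched sub-sampling (RDM)

Sub-samples of `n_cases_sub=100` cases and `n_controls_sub=108` controls
are drawn uniformly without replacement. A sub-sample is accepted iff the
cases and controls within it show no significant difference (all p ≥
0.05) simultaneously in age (Welch t — "t test" with no variance
assumption), education and SES (Pearson chi-square on the level×status
table; a variable constant within the sub-sample counts as balanced with
a warning). Rejection sampling continues until `n_subsamples=1000`
acceptances, with a hard budget of 100× that many attempts — exhaustion
aborts with the acceptance rate, which is the diagnostic for confounding
too strong to match away. A `variables` argument supports single-variable
ensembles (e.g. SES-only matching) as an alternative reading of
"matched by each one of three variables".

Within each accepted sub-sample the SNP-level QC (call rate, MAF) is
re-applied — a SNP too rare inside a sub-sample is skipped there and does
not count as evaluated — and the adjusted logistic model is re-fitted.
Model failures count as non-evaluated, never as significant. A unit is
kept when `fraction_significant` strictly exceeds 50%. Per-sub-sample ORs
are summarized by their median and 2.5–97.5 percentile range, since no
aggregation rule is canonical.

**Dependence caveat.** Sub-samples of 100+108 drawn from ~170/180 share
roughly 60% of their members, so per-sub-sample tests are strongly
positively dependent. The suite's null simulations show the *mean*
fraction of significant sub-samples is well calibrated (~0.05), but any
SNP that reaches a chance full-sample association of p ≲ 0.01 tends to
stay significant in a majority of sub-samples and is then retained by the
50% rule. The RDM keep rule is therefore an evidence summary, not a
family-wise error control: across 50-SNP null panels, roughly a third to
a half of datasets retain at least one SNP. Users should read the RDM
percentage as a stability measure for a finding, not as a calibrated
test.

### Haplotypes

Pairwise LD is computed from EM-estimated two-locus haplotype
frequencies: D = p_AB − p_A p_B, D′ = |D|/D_max, r² = D²/(p_A q_A p_B q_B),
and significance from χ² = 2n·r² on 1 df. Multi-SNP sets (2–6 SNPs;
`significant_ld_groups` gates on pairwise p BH-adjusted within gene at
0.05) are phased probabilistically by the standard EM under
haplotype-level HWE: each individual with h heterozygous sites has
2^(h−1) compatible diplotypes, posterior weights ∝ f(h₁)f(h₂) (doubled
for h₁≠h₂), frequencies re-estimated from expected counts; uniform
initialization over observed-compatible haplotypes; convergence at
max|Δf| < 1e-8 or 1000 iterations; the log-likelihood trace is retained
and is non-decreasing by construction. Frequencies are estimated
separately in cases and controls for reporting, but the haplotype
*dosages* used for testing come from the pooled, phenotype-blind fit to
avoid differential-phasing bias. Association is one-vs-rest per
haplotype on the posterior-mean dosage (0–2) — propagating phase
uncertainty rather than best-guess phasing — with the same covariates as
the SNP scan; haplotypes under 1% pooled frequency are pooled into a
"rare" unit. The haplotype RDM re-runs the EM inside every sub-sample and
matches haplotypes across sub-samples by allele string.

### Structure and power

PCA standardizes each SNP column by center 2p̂ and scale √(2p̂(1−p̂)),
mean-imputes missing dosages, and decomposes by SVD with a deterministic
sign convention (largest-|loading| entry positive). Power uses the
normal approximation for the two-sided two-proportion test at Cohen's h
with the harmonic-mean effective size ñ = 2n₁n₂/(n₁+n₂):
power = Φ(h√(ñ/2) − z₁₋α/₂) + Φ(−h√(ñ/2) − z₁₋α/₂). The published
"effect size 0.26" convention is interpreted as Cohen's h (the convention
of the standard power tooling); `power_for_log_or` offers the
alternative log-OR reading at a user-supplied allele frequency. At
h = 0.26, α = 0.05, n = 172/160 this gives 0.658, verified against a
Monte-Carlo simulation of the test to within 0.01.

## The synthetic-cohort generator

The generator emulates the study conditions: 176 cases / 183 controls,
141 candidate SNPs, predominantly European three-way admixture.

* **Allele frequencies.** Ancestral frequency p ~ U(0.05, 0.5) per SNP;
  population frequencies Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  with F = F_ST = 0.1 (continental scale), clipped to [0.01, 0.99].
* **Admixture.** Individual ancestry ~ Dirichlet(8, 1, 1): mean 80%
  European, matching the 70–90% European contribution typical of the
  populations this design targets.
* **LD blocks.** Four blocks (2–4 SNPs) drawn as whole gamete haplotypes
  from per-population frequency vectors, themselves
  Dirichlet((1−F)/F · base) perturbations of base haplotype frequencies
  on the simplex — the Balding–Nichols construction lifted to haplotypes.
* **Confounders.** SES and education are 3-level ordinals from latent
  Gaussians loading on the European fraction (loadings 1.5 and 1.2,
  thresholds −0.5/0.8); BMI ~ N(26 + 2·(1−anc_EUR), 4²) kg/m²; age is
  N(60, 8²) years truncated below at 45 (the cohort entry age).
* **Disease model.** logit P(case) = b₀ + Σβ·dosage (planted per-allele
  log-ORs log 1.62, 1.45, 1.88, 0.48) + one haplotype effect (log 1.75
  per copy) + 0.35·(SES−2) + 0.20·(edu−2) + 0.02·(age−60). The intercept
  is solved numerically for a ~10% population case rate; individuals are
  then enrolled retrospectively (stream until the case and control quotas
  fill, budget 100× the cohort size), keeping the odds ratio the
  estimand. The SES coefficient (OR ≈ 1.4 per level, ≈ 2 between extreme
  levels) is the strongest imbalance that remains *matchable*: the
  realized SES×status table is significant at cohort scale in a majority
  of replicates, yet every replicate's RDM ensemble completes within the
  attempt budget. Stronger bias occasionally produces cohorts whose
  confounding no rejection-matching scheme can neutralize, which would
  not emulate a study in which the matched ensemble was actually built.
* **Missingness.** Entries are deleted independently at 2% per SNP;
  designated SNPs/samples can carry elevated rates to create guaranteed
  QC casualties.
* **Determinism.** One RNG stream per stage (frequencies, block
  haplotypes, ancestry, gametes, covariates, status, missingness, allele
  letters) spawned from the master seed; emitted PED/MAP/TSV/JSON files
  are bitwise reproducible.

What the generator does **not** emulate: genotyping batch effects and
platform-specific error, relatedness, recombination within blocks,
X-linked markers, age/period structure in recruitment, or real LD decay.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
artifact of real cohort data.

## Numerical choices

* Minor-allele ties (frequency exactly 0.5) break alphabetically;
  monomorphic SNPs take the observed allele as major with the
  alphabetically-first unused base as placeholder minor (they are MAF-
  filtered anyway). Half-missing PED pairs are fully missing, and allele
  frequencies for role assignment count complete pairs only.
* PED genotype pairs are written in alphabetical order so that files are
  byte-stable under re-reading even when a 0.5-frequency SNP flips roles.
* HWE tie handling: tables with conditional probability within 1e-10
  (relative, log scale) of the observed probability count as ties; the
  exhaustive sweep against exact rational enumeration (all tables n ≤ 50)
  confirms 12-digit agreement.
* The EM guards individuals whose diplotype support vanishes numerically
  by falling back to uniform posteriors; frequencies stay on the simplex
  to 1e-8.
* Logistic etas are clipped at ±30 for overflow safety; the batched
  solver adds a 1e-12-scaled ridge to the information matrix only to keep
  exactly-singular (separated) batch members from aborting the solve.

## Problem sizes used by the test suite

Simulation-based checks run at deliberately chosen scales: null RDM
calibration uses 20 cohorts × 50 SNPs × 200 sub-samples (the sub-sample
count scales the Monte-Carlo precision of each fraction, not its
expectation); SNP effect recovery uses 200 replicates at 5000+5000;
haplotype recovery uses 200 replicates at the study's own 172/160 scale;
oracle sweeps are exhaustive (HWE, n ≤ 50) or 100-fold (logistic).

## Known limitations

* The RDM keep rule is not an error-rate control (see the dependence
  caveat above); the package reports it alongside, not instead of, the
  FDR-corrected full-sample analysis.
* Wald CIs for rare haplotypes at n ≈ 330 are approximate; profile
  likelihood would be better below ~1% frequency but those units are
  pooled as "rare" anyway.
* Expected-dosage haplotype tests mildly attenuate effects when phase
  uncertainty is high (low LD); the recovery simulations quantify the
  effect at the study scale.
* PCA on a ~140-SNP candidate panel barely resolves *continuous*
  admixture within a single cohort (tight LD blocks can dominate the
  leading component); it cleanly separates distinct populations at
  F_ST = 0.1, which is what the structure diagnostic is for.
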