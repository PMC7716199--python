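"""Synthetic admixed-cohort generator: frequencies, genotypes, confounders,
retrospective sampling, missingness, determinism."""
import numpy as np
import pytest
from scipy import stats

from admixscan import (LDBlock, SimulationConfig, inject_missingness,
                       ld_pair, null_config, sample_ancestral_freqs,
                       simulate_dataset, simulate_genotypes, stage_rngs,
                       write_covariates, write_ped_map)
from admixscan.simulate import (sample_ancestry, sample_block_pop_freqs,
                                solve_intercept)


class TestAncestralFreqs:
    def test_moments_match_balding_nichols(self):
        rng = np.random.default_rng(0)
        n = 100_000
        freqs = sample_ancestral_freqs(n, 0.1, (0.299999, 0.300001), rng)
        draws = freqs[0]   # one population, n SNPs at base p = 0.3
        mean_se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - 0.3) < 3 * mean_se
        var = draws.var(ddof=1)
        var_se = np.sqrt((np.mean((draws - draws.mean()) ** 4)
                          - var ** 2) / n)
        assert abs(var - 0.1 * 0.3 * 0.7) < 3 * var_se

    def test_small_fst_collapses_to_base(self):
        rng = np.random.default_rng(1)
        freqs = sample_ancestral_freqs(500, 1e-4, (0.2, 0.4), rng)
        assert (freqs.max(axis=0) - freqs.min(axis=0) < 0.05).all()

    def test_seed_determinism(self):
        a = sample_ancestral_freqs(100, 0.1, (0.05, 0.5),
                                   np.random.default_rng(5))
        b = sample_ancestral_freqs(100, 0.1, (0.05, 0.5),
                                   np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_invalid_fst(self):
        with pytest.raises(ValueError):
            sample_ancestral_freqs(10, 0.0, (0.1, 0.4),
                                   np.random.default_rng(0))


class TestGenotypes:
    def test_pure_ancestry_uses_population_frequency(self):
        rng = np.random.default_rng(2)
        anc = np.tile([1.0, 0.0, 0.0], (20_000, 1))
        pop_freqs = np.array([[0.2], [0.8], [0.5]])
        dos, _ = simulate_genotypes(anc, pop_freqs, [], [], rng)
        maf = dos.mean() / 2
        assert maf == pytest.approx(0.2, abs=3 * np.sqrt(0.2 * 0.8 / 40_000))

    def test_two_haplotype_block_gives_complete_ld(self):
        rng = np.random.default_rng(3)
        anc = sample_ancestry(10_000, (8, 1, 1), rng)
        block = LDBlock((0, 1), (0.5, 0.0, 0.0, 0.5))
        popf = np.tile([0.5, 0.0, 0.0, 0.5], (3, 1))
        dos, haps = simulate_genotypes(anc, np.full((3, 2), 0.5), [block],
                                       [popf], rng)
        _, dp, r2, _ = ld_pair(dos[:, 0], dos[:, 1])
        assert r2 > 0.999 and dp > 0.999
        # every gamete haplotype is 00 or 11
        assert set(np.unique(haps[0])) <= {0, 3}

    def test_empirical_maf_matches_mixture_expectation(self):
        rng = np.random.default_rng(4)
        n = 5_000
        anc = sample_ancestry(n, (8, 1, 1), rng)
        pop_freqs = sample_ancestral_freqs(30, 0.1, (0.05, 0.5),
                                           np.random.default_rng(5))
        dos, _ = simulate_genotypes(anc, pop_freqs, [], [], rng)
        expect = (anc @ pop_freqs).mean(axis=0)
        got = dos.mean(axis=0) / 2
        sd = np.sqrt(expect * (1 - expect) / (2 * n))
        assert (np.abs(got - expect) < 4 * sd).all()

    def test_bad_block_frequencies_fatal(self):
        rng = np.random.default_rng(6)
        anc = sample_ancestry(10, (8, 1, 1), rng)
        block = LDBlock((0, 1), (0.5, 0.0, 0.0, 0.5))
        bad = np.tile([0.5, 0.2, 0.0, 0.5], (3, 1))   # sums to 1.2
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_genotypes(anc, np.full((3, 2), 0.5), [block], [bad], rng)


class TestPhenotypes:
    def test_population_case_rate_near_target(self, study_dataset):
        _, _, truth = study_dataset
        # re-derive the rate the solved intercept implies on fresh draws
        assert -5.0 < truth.intercept < -1.0

    def test_intercept_solver(self):
        rng = np.random.default_rng(7)
        linear = rng.normal(0, 0.8, 50_000)
        b0 = solve_intercept(linear, 0.10)
        from scipy.special import expit
        assert expit(b0 + linear).mean() == pytest.approx(0.10, abs=1e-6)

    def test_confounded_config_shows_ses_imbalance(self):
        """The SES x status table is significant in a majority of cohorts —
        the imbalance the randomized sub-sampling is designed to remove."""
        pvals = []
        for seed in range(10):
            cfg = null_config(n_snps=5, confounded=True, seed=seed)
            _, pheno, _ = simulate_dataset(cfg)
            tab = [[(pheno.data.loc[pheno.case_ids, "ses"] == k).sum()
                    for k in (1, 2, 3)],
                   [(pheno.data.loc[pheno.control_ids, "ses"] == k).sum()
                    for k in (1, 2, 3)]]
            pvals.append(stats.chi2_contingency(np.array(tab),
                                                correction=False)[1])
        assert sum(p < 0.05 for p in pvals) >= 5
        assert np.median(pvals) < 0.10

    def test_unconfounded_null_type_one_error(self):
        """With no effects and no confounder bias the adjusted model holds
        its level; the unadjusted allelic test may run slightly hot from
        the Wahlund excess homozygosity of the pooled admixed sample."""
        from admixscan import allelic_test, fit_logistic_many, null_config
        from admixscan.association import ADJUST_COVARIATES
        rej_allelic = rej_model = total = 0
        for seed in range(6):
            cfg = null_config(n_cases=120, n_controls=130, n_snps=30,
                              confounded=False, seed=seed)
            matrix, pheno, _ = simulate_dataset(cfg)
            y = pheno.y
            rej_allelic += sum(
                allelic_test(matrix.dosages[:, j], y)[1] < 0.05
                for j in range(matrix.n_snps))
            fits = fit_logistic_many(
                matrix.dosages, pheno.covariate_matrix(ADJUST_COVARIATES), y)
            rej_model += int((fits["p"] < 0.05).sum())
            total += matrix.n_snps
        assert 0.005 <= rej_model / total <= 0.10
        assert rej_allelic / total <= 0.13


class TestMissingness:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (50, 10)).astype(float)
        cfg = SimulationConfig(missing_rate_snp=1e-12, ld_blocks=[],
                               effects=[], n_snps=10)
        cfg.missing_rate_snp = 0.0
        out = inject_missingness(d, cfg, np.random.default_rng(9))
        assert np.array_equal(out, d)

    def test_rates_within_three_sd(self):
        rng = np.random.default_rng(10)
        d = np.zeros((2000, 20))
        cfg = SimulationConfig(n_snps=20, ld_blocks=[], effects=[],
                               missing_rate_snp=0.05)
        out = inject_missingness(d, cfg, rng)
        count = np.isnan(out).sum()
        n = d.size
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(count - n * 0.05) < 3 * sd

    def test_designated_snps_fail_call_rate_filter(self):
        rng = np.random.default_rng(11)
        d = np.zeros((300, 20))
        cfg = SimulationConfig(n_snps=20, ld_blocks=[], effects=[],
                               missing_rate_snp=0.01,
                               highmiss_snps=(2, 7, 11),
                               highmiss_snp_rate=0.15)
        fails = []
        for seed in range(5):
            out = inject_missingness(d, cfg, np.random.default_rng(seed))
            call = 1 - np.isnan(out).mean(axis=0)
            fails.append((call < 0.90).sum())
            assert set(np.where(call < 0.90)[0]) <= {2, 7, 11}
        assert np.mean(fails) >= 2.5   # binomial expectation ~2.9


class TestDataset:
    def test_requested_counts_and_ancestry_simplex(self, study_dataset):
        matrix, pheno, truth = study_dataset
        assert len(pheno.case_ids) == 176
        assert len(pheno.control_ids) == 183
        assert matrix.n_snps == 141
        anc = pheno.data[["anc_eur", "anc_afr", "anc_nat"]].to_numpy()
        np.testing.assert_allclose(anc.sum(axis=1), 1.0, atol=1e-9)
        # predominantly European ancestry, mean near alpha normalization
        assert 0.7 < anc[:, 0].mean() < 0.9

    def test_bitwise_determinism_of_emitted_files(self, tmp_path):
        cfg = SimulationConfig(n_cases=40, n_controls=40, n_snps=30,
                               ld_blocks=[LDBlock((3, 4), (.4, .1, .1, .4))],
                               effects=[], seed=77)
        payload = []
        for tag in ("a", "b"):
            matrix, pheno, truth = simulate_dataset(cfg)
            ped = tmp_path / f"{tag}.ped"
            mp = tmp_path / f"{tag}.map"
            cov = tmp_path / f"{tag}.tsv"
            write_ped_map(matrix, ped, mp, pheno)
            write_covariates(pheno, cov)
            tj = tmp_path / f"{tag}.json"
            truth.to_json(tj)
            payload.append((ped.read_bytes(), mp.read_bytes(),
                            cov.read_bytes(), tj.read_bytes()))
        assert payload[0] == payload[1]

    def test_stage_rngs_are_stable_streams(self):
        r1 = stage_rngs(3)
        r2 = stage_rngs(3)
        assert r1["gametes"].random(4).tolist() == \
            r2["gametes"].random(4).tolist()
        assert r1["freqs"].random(4).tolist() != \
            r1["covariates"].random(4).tolist()

    def test_block_pop_freqs_on_simplex(self):
        block = LDBlock((0, 1), (0.4, 0.1, 0.1, 0.4))
        f = sample_block_pop_freqs(block, 0.1, np.random.default_rng(12))
        assert f.shape == (3, 4)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(fst=1.5)
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(ld_blocks=[LDBlock((1, 2), (.5, 0, 0, .5)),
                                        LDBlock((2, 3), (.5, 0, 0, .5))])
        with pytest.raises(ValueError, match="out of range"):
            SimulationConfig(n_snps=5, ld_blocks=[], effects=[],
                             confounder_status_bias={}).__class__(
                n_snps=5, ld_blocks=[],
                effects=[__import__("admixscan").EffectSpec("snp", 99, 0.1)])
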