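"""LD estimation, EM haplotype frequencies, haplotype association."""
import numpy as np
import pytest

from admixscan import (RunConfig, em_haplotypes, haplotype_association,
                       haplotype_rdm, ld_pair)
from admixscan.haplotype import _compatible_pairs

from conftest import make_matrix, make_pheno


# ---------------------------------------------------------------------------
# independent likelihood oracle for 2-SNP haplotype frequencies:
# staged grid refinement over the 3-simplex, explicit genotype-class formulas
# ---------------------------------------------------------------------------

def two_snp_loglik(counts, f00, f01, f10, f11):
    """counts[(gA, gB)] genotype-class counts; f_xy = freq of haplotype
    with x = minor at A, y = minor at B (so f10 carries minor at A only)."""
    probs = {
        (0, 0): f00 ** 2, (2, 2): f11 ** 2,
        (2, 0): f10 ** 2, (0, 2): f01 ** 2,
        (1, 0): 2 * f00 * f10, (0, 1): 2 * f00 * f01,
        (1, 2): 2 * f01 * f11, (2, 1): 2 * f10 * f11,
        (1, 1): 2 * f00 * f11 + 2 * f01 * f10,
    }
    ll = 0.0
    for g, c in counts.items():
        if c:
            p = probs[g]
            if p <= 0:
                return -np.inf
            ll += c * np.log(p)
    return ll


def grid_search_two_snp(ga, gb):
    counts = {}
    for a, b in zip(ga.astype(int), gb.astype(int)):
        counts[(a, b)] = counts.get((a, b), 0) + 1

    def evaluate(ax0, ax1, ax2):
        f00, f01, f10 = np.meshgrid(ax0, ax1, ax2, indexing="ij")
        f00, f01, f10 = f00.ravel(), f01.ravel(), f10.ravel()
        f11 = 1.0 - f00 - f01 - f10
        keep = f11 >= -1e-12
        f00, f01, f10, f11 = f00[keep], f01[keep], f10[keep], \
            np.maximum(f11[keep], 0.0)
        probs = {
            (0, 0): f00 ** 2, (2, 2): f11 ** 2,
            (2, 0): f10 ** 2, (0, 2): f01 ** 2,
            (1, 0): 2 * f00 * f10, (0, 1): 2 * f00 * f01,
            (1, 2): 2 * f01 * f11, (2, 1): 2 * f10 * f11,
            (1, 1): 2 * f00 * f11 + 2 * f01 * f10,
        }
        ll = np.zeros(f00.size)
        with np.errstate(divide="ignore", invalid="ignore"):
            for g, c in counts.items():
                if c:
                    ll += c * np.log(probs[g])
        ll[~np.isfinite(ll)] = -np.inf
        best = int(np.argmax(ll))
        return f00[best], f01[best], f10[best], f11[best]

    step = 0.02
    ax = np.arange(0.0, 1.0 + 1e-9, step)
    best = evaluate(ax, ax, ax)
    for step in (0.002, 0.0002):
        # window covers +/- one previous grid step around the incumbent
        axes = [np.arange(max(0.0, v - 10.5 * step),
                          min(1.0, v + 10.5 * step) + 1e-12, step)
                for v in best[:3]]
        best = evaluate(*axes)
    return dict(zip(["00", "01", "10", "11"], best))


def hapset_freqs_by_bits(hapset, matrix, snp_ids):
    """Map EM pooled frequencies onto '00'/'01'/'10'/'11' bit labels."""
    idx = [matrix.snp_index(s) for s in snp_ids]
    snps = [matrix.snps[i] for i in idx]
    out = {"00": 0.0, "01": 0.0, "10": 0.0, "11": 0.0}
    for h, f in zip(hapset.haplotypes, hapset.freq_pooled):
        bits = "".join("1" if ch == s.allele_minor else "0"
                       for ch, s in zip(h, snps))
        # bit order: first SNP is bit 0 -> label 'ab' with a = SNP A state
        out[f"{bits[0]}{bits[1]}"] = float(f)
    return out


class TestEnumeration:
    @pytest.mark.parametrize("g,n_pairs", [
        ([0, 0], 1), ([2, 2], 1), ([1, 0], 1), ([1, 1], 2),
        ([1, 1, 1], 4), ([1, 1, 1, 1], 8), ([2, 1, 0, 1], 2),
    ])
    def test_pair_counts(self, g, n_pairs):
        assert len(_compatible_pairs(np.array(g))) == n_pairs

    def test_pairs_reconstruct_genotype(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = rng.integers(0, 3, size=4)
            for h1, h2 in _compatible_pairs(g):
                rebuilt = [(h1 >> j & 1) + (h2 >> j & 1) for j in range(4)]
                assert rebuilt == list(g)


class TestEM:
    def test_unambiguous_data_equals_direct_counting(self):
        # all homozygous: every gamete is observed directly
        d = np.array([[0, 0], [2, 2], [2, 2], [0, 0], [2, 2]], dtype=float)
        matrix = make_matrix(d)
        hs = em_haplotypes(matrix, ["snp0", "snp1"])
        freqs = dict(zip(hs.haplotypes, hs.freq_pooled))
        assert freqs["GG"] == 4 / 10   # both major
        assert freqs["AA"] == 6 / 10   # both minor
        assert hs.converged

    def test_single_double_het_posterior_follows_frequencies(self):
        # many unambiguous AB/AB and ab/ab plus one double heterozygote:
        # cis phase dominates because f_AB, f_ab >> f_Ab, f_aB
        d = np.array([[2, 2]] * 8 + [[0, 0]] * 8 + [[1, 1]], dtype=float)
        matrix = make_matrix(d)
        hs = em_haplotypes(matrix, ["snp0", "snp1"])
        freqs = dict(zip(hs.haplotypes, hs.freq_pooled))
        assert freqs["AA"] > 0.45 and freqs["GG"] > 0.45
        # the ambiguous individual's expected dosage concentrates on AA/GG
        i = 16
        dos = dict(zip(hs.haplotypes, hs.dosages[i]))
        assert dos["AA"] > 0.98 and dos["GG"] > 0.98

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = rng.integers(10, 60)
            k = rng.integers(2, 5)
            d = rng.integers(0, 3, size=(n, k)).astype(float)
            matrix = make_matrix(d)
            hs = em_haplotypes(matrix, [f"snp{j}" for j in range(k)])
            trace = np.array(hs.loglik_trace)
            assert (np.diff(trace) >= -1e-9).all()
            assert hs.freq_pooled.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.allclose(hs.dosages.sum(axis=1), 2.0, atol=1e-8)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 25
            # correlated pair of SNPs
            h = r.choice(4, size=(n, 2), p=[0.4, 0.1, 0.15, 0.35])
            ga = ((h >> 1) & 1).sum(axis=1).astype(float)
            gb = (h & 1).sum(axis=1).astype(float)
            matrix = make_matrix(np.column_stack([ga, gb]))
            hs = em_haplotypes(matrix, ["snp0", "snp1"])
            got = hapset_freqs_by_bits(hs, matrix, ["snp0", "snp1"])
            want = grid_search_two_snp(ga, gb)
            for key in want:
                assert got.get(key, 0.0) == pytest.approx(want[key], abs=1e-3)

    def test_missing_rows_excluded_and_errors(self):
        d = np.array([[0, 1], [np.nan, 1], [2, 2]], dtype=float)
        hs = em_haplotypes(make_matrix(d), ["snp0", "snp1"])
        assert len(hs.sample_ids) == 2
        with pytest.raises(ValueError):
            em_haplotypes(make_matrix(np.full((3, 2), np.nan)),
                          ["snp0", "snp1"])
        with pytest.raises(ValueError, match="2 to 6"):
            em_haplotypes(make_matrix(d), ["snp0"])


class TestLD:
    def test_independent_snps_near_zero_r2(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.4, 10_000).astype(float)
        D, dp, r2, p = ld_pair(a, b)
        assert r2 < 0.01

    def test_complete_ld_block(self):
        # only AB and ab haplotypes exist
        rng = np.random.default_rng(4)
        hap = rng.binomial(1, 0.5, size=(2000, 2))
        g = hap.sum(axis=1).astype(float)
        D, dp, r2, p = ld_pair(g, g.copy())
        assert dp == pytest.approx(1.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert p < 1e-10

    def test_symmetry_and_relabel_invariance(self):
        rng = np.random.default_rng(5)
        h = rng.choice(4, size=(500, 2), p=[0.35, 0.15, 0.1, 0.4])
        a = ((h >> 1) & 1).sum(axis=1).astype(float)
        b = (h & 1).sum(axis=1).astype(float)
        Dab, dpab, r2ab, pab = ld_pair(a, b)
        Dba, dpba, r2ba, pba = ld_pair(b, a)
        assert r2ab == pytest.approx(r2ba, abs=1e-9)
        assert dpab == pytest.approx(dpba, abs=1e-9)
        # flipping allele coding at one locus preserves r-squared
        _, _, r2flip, _ = ld_pair(2 - a, b)
        assert r2flip == pytest.approx(r2ab, abs=1e-9)

    def test_monomorphic_is_an_error(self):
        a = np.zeros(50)
        b = np.array([0, 1, 2] * 17)[:50].astype(float)
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(a, b)


class TestHaplotypeAssociation:
    def _dataset(self, seed=0, effect=0.0, n=400):
        """Two SNPs in LD; optional log-OR on the doubly-minor haplotype."""
        rng = np.random.default_rng(seed)
        h = rng.choice(4, size=(n, 2), p=[0.4, 0.15, 0.15, 0.3])
        ga = (h & 1).sum(axis=1).astype(float)
        gb = ((h >> 1) & 1).sum(axis=1).astype(float)
        n_target = (h == 3).sum(axis=1)
        from scipy.special import expit
        prob = expit(-0.4 + effect * n_target)
        status = rng.binomial(1, prob)
        matrix = make_matrix(np.column_stack([ga, gb]))
        pheno = make_pheno(n, n_cases=0, rng=rng)
        pheno.data["status"] = np.where(status == 1, "case", "control")
        return matrix, pheno

    def test_null_or_near_one_and_freqs_balance(self):
        matrix, pheno = self._dataset(seed=7, effect=0.0)
        hs = em_haplotypes(matrix, ["snp0", "snp1"], pheno)
        tab = haplotype_association(hs, pheno.subset(hs.sample_ids))
        real = tab[tab["haplotype"] != "rare"]
        assert (np.abs(np.log(real["or_adj"])) < 0.5).all()
        assert np.nansum(hs.freq_cases) == pytest.approx(1.0, abs=1e-8)
        assert (np.nansum(hs.freq_cases - hs.freq_controls)
                == pytest.approx(0.0, abs=1e-8))

    def test_planted_haplotype_effect_recovered(self):
        matrix, pheno = self._dataset(seed=8, effect=np.log(2.0), n=2000)
        hs = em_haplotypes(matrix, ["snp0", "snp1"], pheno)
        tab = haplotype_association(hs, pheno.subset(hs.sample_ids))
        row = tab[tab["haplotype"] == "AA"].iloc[0]   # both minor alleles
        assert row["p"] < 0.01
        assert 1.4 < row["or_adj"] < 2.9

    def test_rare_haplotypes_pooled(self):
        rng = np.random.default_rng(9)
        h = rng.choice(4, size=(300, 2), p=[0.493, 0.005, 0.002, 0.5])
        ga = (h & 1).sum(axis=1).astype(float)
        gb = ((h >> 1) & 1).sum(axis=1).astype(float)
        matrix = make_matrix(np.column_stack([ga, gb]))
        pheno = make_pheno(300, rng=rng)
        hs = em_haplotypes(matrix, ["snp0", "snp1"], pheno)
        tab = haplotype_association(hs, pheno.subset(hs.sample_ids))
        if (hs.freq_pooled < 0.01).any():
            assert "rare" in set(tab["haplotype"])


class TestHaplotypeRDM:
    def test_reproducible_and_aggregated(self):
        from admixscan import build_ensemble
        matrix, pheno = TestHaplotypeAssociation()._dataset(
            seed=10, effect=np.log(2.2), n=400)
        cfg = RunConfig(n_subsamples=20, n_cases_sub=80, n_controls_sub=80)
        res = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            ens = build_ensemble(pheno, cfg, rng)
            res.append(haplotype_rdm(matrix, ["snp0", "snp1"], pheno,
                                     ens, cfg))
        assert res[0].equals(res[1])
        assert (res[0]["fraction_significant"] <= 1).all()
        assert (res[0]["n_significant"] <= res[0]["n_evaluated"]).all()
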