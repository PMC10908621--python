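"""Unit tests for the genotype and sequencing-data GRM estimators."""

import numpy as np
import pytest

import polygrm as pg
from conftest import random_read_counts
from _oracles import grm_genotype_brute, grm_hts_brute, vanraden_diploid


def _gm(values, psi=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return pg.GenotypeMatrix(values, [f"i{k}" for k in range(n)],
                             [f"s{j}" for j in range(m)])


class TestFreqGenotype:
    def test_all_zero_dosages(self):
        g = _gm(np.zeros((3, 2)))
        assert np.allclose(pg.estimate_freq_genotype(g, 4).p, 0.0)

    def test_two_tetraploids(self):
        g = _gm([[1.0], [3.0]])
        assert pg.estimate_freq_genotype(g, 4).p[0] == pytest.approx(0.5)

    def test_mixed_ploidy(self):
        # diploid dosage 2 (-> 1.0) and tetraploid dosage 2 (-> 0.5)
        g = _gm([[2.0], [2.0]])
        p = pg.estimate_freq_genotype(g, [2, 4]).p
        assert p[0] == pytest.approx(0.75)

    def test_missing_aware(self):
        g = _gm([[2.0], [np.nan]])
        assert pg.estimate_freq_genotype(g, [4, 4]).p[0] == pytest.approx(0.5)


class TestFreqReads:
    def test_all_reference(self):
        rc = pg.ReadCounts([[5], [3]], [[5], [3]], ["a", "b"], ["s"])
        assert pg.estimate_freq_reads(rc, 0.0).p[0] == pytest.approx(1.0)

    def test_error_adjustment_fixed_point(self):
        # q = 0.5 is invariant under the error adjustment
        rc = pg.ReadCounts([[5], [5]], [[10], [10]], ["a", "b"], ["s"])
        assert pg.estimate_freq_reads(rc, 0.01).p[0] == pytest.approx(0.5)

    def test_clamped_to_zero(self):
        # raw ratio 0.005 below eps=0.01 clamps to 0
        rc = pg.ReadCounts([[1]], [[200]], ["a"], ["s"])
        assert pg.estimate_freq_reads(rc, 0.01).p[0] == 0.0

    def test_unadjusted_mode_returns_ratio(self):
        rc = pg.ReadCounts([[3]], [[10]], ["a"], ["s"])
        assert pg.estimate_freq_reads(rc, 0.01, adjust=False).p[0] == pytest.approx(0.3)

    def test_zero_depth_snp_flagged(self):
        rc = pg.ReadCounts([[0, 1]], [[0, 2]], ["a"], ["s1", "s2"])
        p = pg.estimate_freq_reads(rc).p
        assert np.isnan(p[0]) and p[1] == pytest.approx(0.5)


class TestGrmGenotype:
    def test_hand_example_two_tetraploids(self):
        # X1=(4,0), X2=(0,2), p=(0.5,0.25): sum p(1-p)=0.4375,
        # G11 = (4 + 1)/(4*0.4375) = 2.857142..., G12 = (-4 - 1)/(4*0.4375)
        g = _gm([[4.0, 0.0], [0.0, 2.0]])
        p = pg.AlleleFreqs([0.5, 0.25])
        grm = pg.grm_genotype(g, 4, p)
        assert grm.values[0, 0] == pytest.approx(20 / 7)
        assert grm.values[0, 1] == pytest.approx(-20 / 7)
        assert np.all(grm.n_snps_used == 2)

    def test_centering_identity(self, rng):
        # X_ij = psi_i p_j exactly -> every entry 0
        p = np.array([0.5, 0.25, 0.75])
        psi = np.array([4, 4, 8])
        g = _gm(np.outer(psi, p))
        grm = pg.grm_genotype(g, psi, pg.AlleleFreqs(p))
        assert np.allclose(grm.values, 0.0)

    def test_diploid_reduces_to_classical_vanraden(self, rng):
        x = rng.binomial(2, 0.4, size=(6, 40)).astype(float)
        p = rng.uniform(0.1, 0.9, 40)
        grm = pg.grm_genotype(_gm(x), 2, pg.AlleleFreqs(p))
        assert np.allclose(grm.values, vanraden_diploid(x, p), rtol=1e-12)

    def test_scaled_tetraploid_proportional_to_diploid(self, rng):
        # X_tetra = 2 * X_diploid shares the dosage proportions R, so in the
        # R representation the estimators coincide up to the ploidy prefactor
        # sqrt(psi_h psi_i): G_tetra = (4/2) * G_diploid exactly.
        x2 = rng.binomial(2, 0.5, size=(5, 30)).astype(float)
        p = rng.uniform(0.1, 0.9, 30)
        g2 = pg.grm_genotype(_gm(x2), 2, pg.AlleleFreqs(p))
        g4 = pg.grm_genotype(_gm(2 * x2), 4, pg.AlleleFreqs(p))
        assert np.allclose(2.0 * g2.values, g4.values, rtol=1e-12)

    def test_noninformative_snps_dropped(self):
        g = _gm([[4.0, 1.0], [0.0, 3.0]])
        grm = pg.grm_genotype(g, 4, pg.AlleleFreqs([1.0, 0.5]))
        assert np.all(grm.n_snps_used == 1)

    def test_matches_bruteforce_with_missingness(self, rng):
        psi = np.array([2, 4, 4, 6, 4])
        p = rng.uniform(0.05, 0.95, 25)
        x = rng.binomial(psi[:, None], p[None, :]).astype(float)
        x[rng.random(x.shape) < 0.3] = np.nan
        grm = pg.grm_genotype(_gm(x), psi, pg.AlleleFreqs(p))
        ref = grm_genotype_brute(x, psi, p)
        assert np.allclose(grm.values, ref, rtol=1e-10, equal_nan=True)

    def test_pair_with_no_shared_snps_is_missing(self):
        x = np.array([[2.0, np.nan], [np.nan, 2.0]])
        grm = pg.grm_genotype(_gm(x), 4, pg.AlleleFreqs([0.5, 0.5]))
        assert np.isnan(grm.values[0, 1])
        assert grm.n_snps_used[0, 1] == 0


class TestGrmHts:
    def test_hand_example_single_snp(self):
        # p=0.5, eps=0: two tetraploids with S=1 and S=0
        rc = pg.ReadCounts([[10], [0]], [[10], [10]], ["a", "b"], ["s"])
        grm = pg.grm_hts(rc, 4, 0.0, pg.AlleleFreqs([0.5]))
        assert grm.values[0, 1] == pytest.approx(-4.0)

    def test_high_depth_limit_equals_genotype_grm(self, rng):
        # exact reads Y = d * X / psi at huge depth: the correction terms vanish
        psi = 4
        p = rng.uniform(0.1, 0.9, 50)
        x = rng.binomial(psi, np.broadcast_to(p, (8, 50)))
        d = np.full(x.shape, 10**8, dtype=np.int64)
        y = d // psi * x
        rc = pg.ReadCounts(y, d, [f"i{k}" for k in range(8)],
                           [f"s{j}" for j in range(50)])
        hts = pg.grm_hts(rc, psi, 0.0, pg.AlleleFreqs(p))
        geno = pg.grm_genotype(_gm(x), psi, pg.AlleleFreqs(p))
        assert np.allclose(hts.values, geno.values, atol=1e-6)

    def test_depth_invariance_of_offdiagonals(self, rng):
        # S is unchanged under (Y, d) -> (kY, kd), so off-diagonals are too
        rc, _, p = random_read_counts(rng)
        freqs = pg.AlleleFreqs(p)
        g1 = pg.grm_hts(rc, 4, 0.01, freqs)
        rc2 = pg.ReadCounts(3 * rc.ref_reads, 3 * rc.depth,
                            rc.individual_ids, rc.snp_ids)
        g2 = pg.grm_hts(rc2, 4, 0.01, freqs)
        off = ~np.eye(rc.n_individuals, dtype=bool)
        assert np.array_equal(g1.values[off], g2.values[off])

    def test_matches_bruteforce_with_missingness(self, rng):
        rc, _, p = random_read_counts(rng, n=6, m=25, mean_depth=3.0, eps=0.01)
        psi = np.full(6, 4)
        eps = np.full(25, 0.01)
        grm = pg.grm_hts(rc, psi, eps, pg.AlleleFreqs(p))
        ref = grm_hts_brute(rc.ref_reads, rc.depth, psi, eps, p)
        assert np.allclose(grm.values, ref, rtol=1e-10, equal_nan=True)

    def test_low_depth_individual_diagonal_missing(self):
        y = np.array([[1, 0], [2, 2]])
        d = np.array([[1, 1], [4, 4]])
        grm = pg.grm_hts(pg.ReadCounts(y, d, ["a", "b"], ["s1", "s2"]),
                         4, 0.0, pg.AlleleFreqs([0.5, 0.5]))
        assert np.isnan(grm.values[0, 0])  # depths 0/1 carry no inbreeding info
        assert not np.isnan(grm.values[0, 1])

    def test_diagonal_term_unbiased_by_enumeration(self):
        # Exact expectation over X ~ Bin(psi, p), Y | X ~ Bin(d, pi):
        # E[((S-p)^2 - A) / (gamma delta)] = p (1 - p) / psi under HWE
        # (the psi factor in G_ii then makes the diagonal unbiased at 1).
        from scipy import stats
        psi, d, eps, p = 4, 3, 0.05, 0.3
        gamma = 1 - 4 * eps * (1 - eps)
        eta = 1 - 4 * p * (1 - p)
        delta = 1 - 1 / d
        a = p * (1 - p) * (1 - gamma * delta) + eps * (eta - (1 - eps) * delta)
        expect = 0.0
        for x in range(psi + 1):
            pi = (x / psi) * (1 - eps) + (1 - x / psi) * eps
            for y in range(d + 1):
                w = stats.binom.pmf(x, psi, p) * stats.binom.pmf(y, d, pi)
                expect += w * ((y / d - p) ** 2 - a) / (gamma * delta)
        assert expect == pytest.approx(p * (1 - p) / psi, rel=1e-12)

    def test_offdiagonal_term_centered_by_enumeration(self):
        # E[(S_h - p)(S_i - p)] = eps^2 eta for unrelated individuals.
        from scipy import stats
        psi, d, eps, p = 4, 2, 0.1, 0.3
        eta = 1 - 4 * p * (1 - p)
        es = 0.0
        for x in range(psi + 1):
            pi = (x / psi) * (1 - eps) + (1 - x / psi) * eps
            for y in range(d + 1):
                es += stats.binom.pmf(x, psi, p) * stats.binom.pmf(y, d, pi) * (y / d - p)
        assert es * es == pytest.approx(eps**2 * eta, rel=1e-10)

    def test_rejects_eps_half(self, rng):
        rc, _, p = random_read_counts(rng)
        with pytest.raises(ValueError, match="0.5"):
            pg.grm_hts(rc, 4, 0.5, pg.AlleleFreqs(p))


class TestPipeline:
    def test_dosage_dispatch(self, rng):
        _, g, _ = random_read_counts(rng)
        auto = pg.grm_pipeline(g, 4)
        manual = pg.grm_genotype(g, 4, pg.estimate_freq_genotype(g, 4))
        assert np.allclose(auto.values, manual.values, equal_nan=True)
        assert auto.metadata["freq_source"] == "genotype-estimated"

    def test_counts_dispatch(self, rng):
        rc, _, _ = random_read_counts(rng)
        auto = pg.grm_pipeline(rc, 4, eps=0.0)
        manual = pg.grm_hts(rc, 4, 0.0, pg.estimate_freq_reads(rc, 0.0))
        assert np.allclose(auto.values, manual.values, equal_nan=True)

    def test_supplied_freqs_passthrough(self, rng):
        rc, _, p = random_read_counts(rng)
        freqs = pg.AlleleFreqs(p)
        assert np.allclose(pg.grm_pipeline(rc, 4, 0.0, freqs).values,
                           pg.grm_hts(rc, 4, 0.0, freqs).values, equal_nan=True)

    def test_rejects_unknown_type(self):
        with pytest.raises(TypeError):
            pg.grm_pipeline(np.zeros((2, 2)), 4)
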