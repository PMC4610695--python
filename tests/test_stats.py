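"""Unit and property tests for the score statistic and its Kendall form."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from atemp import (
    batch_score_statistics,
    genotype_freqs,
    genotype_weights,
    kendall_tau_statistic,
    permutation_pvalue,
    score_statistic,
)
from tests.conftest import random_instance

genotype_vectors = st.lists(
    st.integers(0, 2), min_size=3, max_size=60
).filter(lambda g: len(set(g)) >= 2)


class TestGenotypeWeights:
    @pytest.mark.parametrize("g,expected", [
        ([0, 0, 1, 2], [0.5, 0.5, -0.25, -0.75]),
        ([0, 1, 2], [2 / 3, 0.0, -2 / 3]),
    ])
    def test_hand_computed_weights(self, g, expected):
        np.testing.assert_allclose(genotype_weights(g), expected, atol=1e-15)

    @given(genotype_vectors)
    def test_weights_sum_to_zero(self, g):
        assert abs(genotype_weights(g).sum()) < 1e-12

    @given(genotype_vectors)
    def test_appendix_variance_identity(self, g):
        """Mean square of the weights equals (1-pi0)(1-pi1)(1-pi2)."""
        pi0, pi1, pi2 = genotype_freqs(g)
        gbar = genotype_weights(g)
        expected = (1 - pi0) * (1 - pi1) * (1 - pi2)
        assert np.mean(gbar ** 2) == pytest.approx(expected, abs=1e-12)

    def test_appendix_identity_hand_value(self):
        # pi = (0.5, 0.25, 0.25) gives 0.5 * 0.75 * 0.75 = 0.28125
        gbar = genotype_weights([0, 0, 1, 2])
        assert np.mean(gbar ** 2) == pytest.approx(0.28125, abs=1e-15)

    def test_monomorphic_raises_with_variant_name(self):
        with pytest.raises(ValueError, match="rs42"):
            genotype_weights([1, 1, 1, 1], variant="rs42")

    def test_two_genotype_classes_allowed(self):
        gbar = genotype_weights([0, 0, 1, 1])
        assert abs(gbar.sum()) < 1e-15


class TestScoreStatistic:
    def test_hand_computed_univariate(self):
        res = score_statistic([1, 2, 3], [0, 1, 2])
        assert res.statistic == pytest.approx(3.0, rel=1e-12)
        assert res.df == 1
        assert res.p_asymptotic == pytest.approx(sps.chi2.sf(3.0, 1), rel=1e-12)
        assert res.n_used == 3

    def test_location_invariance(self, make_instance):
        y, g = make_instance(n=60, k=3)
        base = score_statistic(y, g).statistic
        shifted = y + np.array([5.0, -3.0, 100.0])
        assert score_statistic(shifted, g).statistic == pytest.approx(
            base, rel=1e-10)

    def test_scale_invariance(self, make_instance):
        y, g = make_instance(n=60, k=3)
        base = score_statistic(y, g).statistic
        scaled = y * np.array([0.1, 7.0, 100.0])
        assert score_statistic(scaled, g).statistic == pytest.approx(
            base, rel=1e-8)

    def test_null_distribution_is_chi_square(self, rng):
        """Independent genotype and phenotypes: S ~ chi2(K) (KS at 1%)."""
        reps, n, k = 5000, 200, 2
        g = rng.binomial(2, 0.3, size=(reps, n))
        y = rng.standard_normal((reps, n, k))
        stats = batch_score_statistics(y, g)
        assert sps.kstest(stats, sps.chi2(k).cdf).pvalue > 0.01

    def test_singular_covariance_raises(self, rng):
        g = rng.binomial(2, 0.3, 50)
        g[0], g[1] = 0, 1
        col = rng.standard_normal(50)
        y = np.column_stack([col, 2 * col])  # collinear
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            score_statistic(y, g)

    def test_constant_column_raises(self):
        with pytest.raises(ValueError, match="constant"):
            score_statistic(np.ones((4, 1)), [0, 1, 2, 1])

    def test_row_mismatch_raises(self):
        with pytest.raises(ValueError, match="match"):
            score_statistic(np.random.default_rng(0).normal(size=(5, 2)),
                            [0, 1, 2])


class TestKendallEquivalence:
    def test_hand_computed_univariate(self):
        res = kendall_tau_statistic([1, 2, 3], [0, 1, 2])
        assert res.statistic == pytest.approx(3.0, rel=1e-12)

    def test_matches_score_statistic(self, rng):
        for _ in range(100):
            y, g = random_instance(rng)
            s1 = score_statistic(y, g).statistic
            s2 = kendall_tau_statistic(y, g).statistic
            assert abs(s1 - s2) / max(s1, 1.0) < 1e-10

    def test_pairwise_u_statistic_oracle(self, rng):
        """U evaluated literally as the double sum over pairs (sign kernel
        for genotype, identity for phenotype) is proportional to the
        weighted sum W = sum_i gbar_i Y_i with constant 2/(n-1)."""
        for _ in range(50):
            n = int(rng.integers(3, 9))
            y, g = random_instance(rng, n=n, k=2)
            u = np.zeros(2)
            for i in range(n):
                for j in range(i):
                    u += np.sign(g[j] - g[i]) * (y[i] - y[j])
            u *= 2.0 / (n * (n - 1))
            w = genotype_weights(g) @ y
            np.testing.assert_allclose(u, 2.0 / (n - 1) * w, atol=1e-12)


class TestBatch:
    def test_batch_matches_single(self, rng):
        reps, n, k = 20, 80, 3
        g = rng.binomial(2, 0.25, size=(reps, n))
        y = rng.standard_normal((reps, n, k))
        batch = batch_score_statistics(y, g)
        single = [score_statistic(y[i], g[i]).statistic for i in range(reps)]
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_batch_monomorphic_raises(self, rng):
        g = rng.binomial(2, 0.3, size=(5, 30))
        g[2] = 0
        y = rng.standard_normal((5, 30, 2))
        with pytest.raises(ValueError, match="monomorphic"):
            batch_score_statistics(y, g)


class TestPermutation:
    def test_deterministic_given_seed(self, make_instance):
        y, g = make_instance(n=50, k=2)
        a = permutation_pvalue(y, g, n_permutations=200, seed=11)
        b = permutation_pvalue(y, g, n_permutations=200, seed=11)
        assert a.p_permutation == b.p_permutation

    def test_counting_formula_lower_bound(self, rng):
        """A statistic exceeding every permuted value gives p = 1/(1+B)."""
        n = 400
        g = rng.binomial(2, 0.3, n)
        y = 1.0 * g + 0.05 * rng.standard_normal(n)  # overwhelming effect
        res = permutation_pvalue(y, g, n_permutations=200, seed=3)
        assert res.p_permutation == pytest.approx(1.0 / 201)

    def test_too_few_permutations_rejected(self, make_instance):
        y, g = make_instance(n=20, k=1)
        with pytest.raises(ValueError, match="100"):
            permutation_pvalue(y, g, n_permutations=10, seed=0)

    def test_null_pvalues_roughly_uniform(self, rng):
        """Mean permutation p-value near 1/2 on null datasets."""
        pvals = []
        for _ in range(40):
            y, g = random_instance(rng, n=60, k=1)
            pvals.append(
                permutation_pvalue(y, g, n_permutations=199, seed=5)
                .p_permutation)
        se = np.sqrt(1.0 / 12 / len(pvals))
        assert abs(np.mean(pvals) - 0.5) < 3.5 * se

    def test_agrees_with_asymptotic_for_normal_data(self, rng):
        """Spearman correlation > 0.99 between asymptotic and permutation
        p-values across datasets of n=500 normal phenotypes."""
        p_asym, p_perm = [], []
        for i in range(60):
            y, g = random_instance(rng, n=500, k=2)
            res = permutation_pvalue(y, g, n_permutations=2000, seed=100 + i)
            p_asym.append(res.p_asymptotic)
            p_perm.append(res.p_permutation)
        rho = sps.spearmanr(p_asym, p_perm).statistic
        assert rho > 0.99
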