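"""Statistical kernel: size factors, dispersion, exact NB test, FDR, rank tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from transgen_nhg.stats_core import (
    ALPHA_FLOOR,
    _exact_p,
    bh_fdr,
    chi_square_gof,
    estimate_dispersion,
    nb_exact_test,
    size_factors,
    spearman_trend,
    wilcoxon_one_sided,
)


class TestSizeFactors:
    def test_identical_columns_are_unity(self):
        m = np.array([[5, 5], [9, 9], [2, 2]])
        assert size_factors(m) == pytest.approx([1.0, 1.0])

    def test_doubled_column(self):
        m = np.array([[10, 20], [4, 8]])
        s = size_factors(m)
        assert s == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert s[1] / s[0] == pytest.approx(2.0)

    def test_single_gene_median_of_ratios(self):
        # geometric mean 6, ratios 4/6 and 9/6
        s = size_factors(np.array([[4, 9]]))
        assert s == pytest.approx([4 / 6, 9 / 6])

    def test_no_all_positive_gene_is_an_error(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(np.array([[0, 5], [3, 0]]))

    @given(c=st.floats(min_value=0.25, max_value=4.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(0)
        m = rng.poisson(50, size=(100, 3)).astype(float) + 1
        scaled = m * np.array([1.0, c, 1.0])
        s0 = size_factors(m)
        s1 = size_factors(scaled)
        # equal up to the geometric-mean-1 convention
        assert s1[1] / s1[0] == pytest.approx(c * s0[1] / s0[0], rel=1e-9)


class TestDispersion:
    def _sim(self, alpha, n=5, genes=2000, mean=80, seed=0):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(np.log(mean), 1.0, genes))
        if alpha == 0:
            counts = rng.poisson(mu[:, None] * np.ones(2 * n)[None, :])
        else:
            r = 1 / alpha
            m = mu[:, None] * np.ones(2 * n)[None, :]
            counts = rng.negative_binomial(r, r / (r + m))
        return counts, [np.arange(n), np.arange(n, 2 * n)]

    def test_poisson_counts_near_floor(self):
        counts, groups = self._sim(alpha=0.0)
        alphas = estimate_dispersion(counts, np.ones(10), groups)
        assert np.median(alphas) <= 0.01

    def test_nb_dispersion_recovered(self):
        counts, groups = self._sim(alpha=0.2)
        alphas = estimate_dispersion(counts, np.ones(10), groups)
        assert 0.1 <= np.median(alphas) <= 0.4

    def test_constant_counts_hit_floor(self):
        counts = np.full((50, 6), 7)
        alphas = estimate_dispersion(counts, np.ones(6), [np.arange(3), np.arange(3, 6)])
        assert np.all(alphas == ALPHA_FLOOR)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            estimate_dispersion(np.ones((5, 3)), np.ones(3), [[0], [1, 2]])


def _brute_exact_p(k_a, k_b, s_a, s2_a, s_b, s2_b, alpha):
    """Plain-float enumeration over all splits of K — the defining formula."""
    K = k_a + k_b
    q = K / (s_a + s_b)

    def pmf(k, mu, a_eff):
        if a_eff < 1e-12:
            return stats.poisson.pmf(k, mu)
        r = 1 / a_eff
        return stats.nbinom.pmf(k, r, r / (r + mu))

    aa = alpha * s2_a / s_a**2
    ab = alpha * s2_b / s_b**2
    probs = np.array([pmf(a, q * s_a, aa) * pmf(K - a, q * s_b, ab) for a in range(K + 1)])
    obs = probs[k_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-8)].sum() / probs.sum())


class TestNbExactTest:
    def test_balanced_counts_give_p_one(self):
        p = nb_exact_test([5, 5], [5, 5], np.ones(2), np.ones(2), 0.1)
        assert p == pytest.approx(1.0)

    def test_all_zero_total_gives_p_one(self):
        assert nb_exact_test([0, 0], [0, 0], np.ones(2), np.ones(2), 0.1) == 1.0

    def test_symmetry_under_group_swap(self):
        a, b = [3, 7, 1], [20, 25, 18]
        sfa, sfb = np.ones(3), np.ones(3)
        assert nb_exact_test(a, b, sfa, sfb, 0.15) == pytest.approx(
            nb_exact_test(b, a, sfb, sfa, 0.15)
        )

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], np.ones(1), np.ones(1), -0.1)

    @pytest.mark.parametrize("alpha", [0.0, 0.05, 0.3])
    @pytest.mark.parametrize("ka,kb", [(0, 10), (3, 12), (25, 25), (1, 49)])
    def test_matches_enumeration_oracle(self, alpha, ka, kb):
        s_a, s2_a = 3.2, 3.5
        s_b, s2_b = 2.8, 2.7
        got = _exact_p(ka, kb, s_a, s2_a, s_b, s2_b, alpha)
        want = _brute_exact_p(ka, kb, s_a, s2_a, s_b, s2_b, alpha)
        assert got == pytest.approx(want, abs=1e-10)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_hand_step_up_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 1.0])
        assert q == pytest.approx([0.04, 0.04, 0.04, 1.0])

    def test_all_equal_ps(self):
        q = bh_fdr([0.2, 0.2, 0.2])
        assert q == pytest.approx([0.2, 0.2, 0.2])

    def test_q_at_least_p_and_capped(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_null_uniform_fdr_control(self):
        """Fraction of 2000 true-null p-values at q <= 0.1 stays near/below 0.1."""
        rng = np.random.default_rng(11)
        fractions = []
        for _ in range(100):
            q = bh_fdr(rng.random(2000))
            fractions.append(np.mean(q <= 0.1))
        se = np.std(fractions) / np.sqrt(len(fractions))
        assert np.mean(fractions) <= 0.1 + 3 * se


class TestWilcoxon:
    def test_exact_small_case(self):
        # all C(4,2)=6 rank splits; only {1,2} has a sum <= 3
        assert wilcoxon_one_sided([1, 2], [3, 4], "less") == pytest.approx(1 / 6)

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 3.0]
        assert wilcoxon_one_sided(x, x, "greater") >= 0.5

    def test_greater_plus_less_at_least_one(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=7)
        pg = wilcoxon_one_sided(x, y, "greater")
        pl = wilcoxon_one_sided(x, y, "less")
        assert pg + pl >= 1.0

    def test_approximation_close_to_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x, y = rng.normal(size=8), rng.normal(0.5, size=8)
            exact = wilcoxon_one_sided(x, y, "greater", exact=True)
            approx = wilcoxon_one_sided(x, y, "greater", exact=False)
            assert approx == pytest.approx(exact, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0], "greater")


class TestChiSquare:
    def test_identity_fit(self):
        stat, p = chi_square_gof([10, 20, 30], [10, 20, 30])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_hand_computation(self):
        stat, p = chi_square_gof([10, 0], [5, 5])
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(stats.chi2.sf(10, 1))

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([1, 2], [0, 3])

    def test_null_calibration_uniform(self):
        # large per-category expectations keep the statistic effectively
        # continuous, so the null p-values should pass a KS uniformity test
        rng = np.random.default_rng(23)
        ps = []
        for _ in range(10_000):
            obs = rng.multinomial(1000, [0.2] * 5)
            ps.append(chi_square_gof(obs, [0.2] * 5)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSpearmanTrend:
    def test_monotone_series(self):
        rho, p = spearman_trend([1, 2, 3, 4, 5, 6])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 720)

    def test_reversed_series_not_significant(self):
        rho, p = spearman_trend([6, 5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p > 0.95
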