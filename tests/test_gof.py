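"""Berk-Jones / Generalized Berk-Jones statistics, p-values, comparators."""

import numpy as np
import pytest
from scipy.stats import binom, chi2, multivariate_normal, norm

from conftest import exchangeable
from gbjgsa.containers import CorrMatrix
from gbjgsa.exceedance import two_sided_pi
from gbjgsa.gof import (
    bj_statistic,
    bj_test,
    comparator_tests,
    gbj_pvalue,
    gbj_statistic,
    gbj_test,
    ghc_statistics_batch,
    ghc_test,
    gof_critical_value,
    gof_statistics_batch,
    minp_test,
    quadratic_test,
    single_z_pvalue,
)


def bj_enumeration_oracle(z):
    """Hand-rolled per-index BJ evaluation with explicit binomial pmfs."""
    z = np.asarray(z, float)
    d = len(z)
    absz = np.sort(np.abs(z))[::-1]
    best = 0.0
    for j in range(1, d // 2 + 1):
        t = absz[j - 1]
        pi0 = 2 * norm.sf(t)
        if not pi0 < j / d:
            continue
        from scipy.optimize import brentq

        mu = brentq(lambda m: 1 - (norm.cdf(t - m) - norm.cdf(-t - m)) - j / d,
                    0, t + 12, xtol=1e-13)
        pi1 = 1 - (norm.cdf(t - mu) - norm.cdf(-t - mu))
        term = binom.logpmf(j, d, pi1) - binom.logpmf(j, d, pi0)
        best = max(best, term)
    return best


class TestBJStatistic:
    def test_no_qualifying_index_gives_zero(self):
        res = bj_statistic(np.array([0.1, -0.2, 0.15, 0.05]))
        assert res.statistic == 0.0

    def test_matches_enumeration_oracle_small(self):
        z = np.array([0.1, 0.2, 3.0, 3.5])
        assert bj_statistic(z).statistic == pytest.approx(
            bj_enumeration_oracle(z), abs=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_oracle_random(self, seed):
        z = np.random.default_rng(seed).standard_normal(11) * 1.4
        assert bj_statistic(z).statistic == pytest.approx(
            bj_enumeration_oracle(z), abs=1e-10
        )

    def test_permutation_and_sign_invariance(self, rng):
        z = rng.standard_normal(9) * 1.5
        base = bj_statistic(z).statistic
        perm = rng.permutation(z) * rng.choice([-1, 1], size=9)
        assert bj_statistic(perm).statistic == pytest.approx(base, abs=1e-12)

    def test_requires_two_statistics(self):
        with pytest.raises(ValueError):
            bj_statistic(np.array([1.0]))


def gbj_term_oracle(z, sigma):
    """Independent re-implementation of the GBJ terms.

    Pairwise orthant probabilities via scipy MVN rectangles, variance
    matching, and the product-form extended beta-binomial pmf.
    """
    from scipy.optimize import brentq

    z = np.asarray(z, float)
    d = len(z)
    absz = np.sort(np.abs(z))[::-1]

    def pair_orthant(t, mu, r):
        cov = np.array([[1.0, r], [r, 1.0]])
        m = np.array([mu, mu])
        rect = lambda lo, hi: multivariate_normal.cdf(hi, mean=m, cov=cov,
                                                      lower_limit=lo)
        big = 30.0
        return (rect([t, t], [big, big]) + rect([t, -big], [big, -t])
                + rect([-big, t], [-t, big]) + rect([-big, -big], [-t, -t]))

    def ebb_lp(s, n, piv, rho):
        g = rho / (1 - rho) if rho > 0 else 0.0
        from scipy.special import gammaln

        val = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
        for i in range(s):
            val += np.log(piv + i * g)
        for i in range(n - s):
            val += np.log(1 - piv + i * g)
        for i in range(n):
            val -= np.log(1 + i * g)
        return val

    def rho_at(t, mu):
        piv = 1 - (norm.cdf(t - mu) - norm.cdf(-t - mu))
        pair = 0.0
        for a in range(d):
            for b in range(d):
                if a != b:
                    pair += pair_orthant(t, mu, sigma[a, b]) - piv**2
        base = d * piv * (1 - piv)
        return max(pair / (base * (d - 1)), 0.0)

    best = 0.0
    for j in range(1, d // 2 + 1):
        t = absz[j - 1]
        pi0 = 2 * norm.sf(t)
        if not pi0 < j / d:
            continue
        mu = brentq(lambda m: 1 - (norm.cdf(t - m) - norm.cdf(-t - m)) - j / d,
                    0, t + 12, xtol=1e-13)
        term = ebb_lp(j, d, j / d, rho_at(t, mu)) - ebb_lp(j, d, pi0, rho_at(t, 0.0))
        best = max(best, term)
    return best


class TestGBJStatistic:
    def test_reduces_to_bj_at_identity(self, rng):
        for _ in range(5):
            z = rng.standard_normal(10) * 1.5
            sbj = bj_statistic(z).statistic
            sgbj = gbj_statistic(z, CorrMatrix.identity(10)).statistic
            assert sgbj == pytest.approx(sbj, abs=1e-10)

    def test_matches_independent_reimplementation(self, rng):
        d = 10
        sigma = exchangeable(d, 0.3)
        z = rng.standard_normal(d) * 1.3
        z[0] = 2.7
        exact = gbj_statistic(z, CorrMatrix(sigma), exact=True).statistic
        fast = gbj_statistic(z, CorrMatrix(sigma)).statistic
        oracle = gbj_term_oracle(z, sigma)
        assert exact == pytest.approx(oracle, abs=1e-7)
        # the spline-cached fast path trades ~1e-3 of statistic accuracy
        assert fast == pytest.approx(exact, abs=2e-3)

    def test_permutation_invariance_with_matching_sigma(self, rng):
        d = 8
        sigma = 0.6 ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))
        z = rng.standard_normal(d) * 1.5
        perm = rng.permutation(d)
        res1 = gbj_test(z, CorrMatrix(sigma))
        res2 = gbj_test(z[perm], CorrMatrix(sigma[np.ix_(perm, perm)]))
        assert res2.statistic == pytest.approx(res1.statistic, abs=1e-12)
        assert res2.p_value == pytest.approx(res1.p_value, rel=1e-9)

    def test_sign_flip_leaves_pvalue_nearly_unchanged(self, rng):
        # flipping z signs with matching Sigma rows/cols changes the
        # shifted-mean count model (signed correlations), so only approximate
        # p-value agreement is expected; BJ is exactly sign-invariant
        d = 8
        sigma = exchangeable(d, 0.4)
        flip = np.diag(np.where(np.arange(d) % 2 == 0, -1.0, 1.0))
        for _ in range(3):
            z = rng.standard_normal(d) * 1.5
            r1 = gbj_test(z, CorrMatrix(sigma))
            r2 = gbj_test(flip @ z, CorrMatrix(flip @ sigma @ flip))
            assert r2.p_value == pytest.approx(r1.p_value, abs=0.02)
            b1 = bj_statistic(z).statistic
            b2 = bj_statistic(flip @ z).statistic
            assert b2 == pytest.approx(b1, abs=1e-12)

    def test_batch_statistics_agree_with_scalar_path(self, rng):
        d = 12
        cm = CorrMatrix(exchangeable(d, 0.3))
        Z = rng.standard_normal((20, d)) * 1.4
        batch = gof_statistics_batch(Z, cm)
        single = np.array([gbj_statistic(z, cm).statistic for z in Z])
        assert np.allclose(batch, single, atol=1e-10)


class TestPValues:
    def test_zero_statistic_gives_p_one(self):
        res = bj_statistic(np.array([0.05, -0.1, 0.02, 0.08]))
        assert gbj_pvalue(res, 4, CorrMatrix.identity(4)) == 1.0

    def test_independent_case_matches_monte_carlo(self, rng):
        d = 10
        z = np.array([0.3, -0.5, 1.1, 2.2, -2.5, 0.2, 1.8, -0.7, 2.9, 0.4])
        res = bj_test(z)
        stats = gof_statistics_batch(
            np.random.default_rng(577215).standard_normal((100_000, d)), None)
        emp = float((stats >= res.statistic - 1e-12).mean())
        se = np.sqrt(emp * (1 - emp) / 100_000)
        assert res.p_value == pytest.approx(emp, abs=3 * se)

    def test_monotone_in_statistic(self):
        d = 10
        cm = CorrMatrix(exchangeable(d, 0.3))
        scales = [0.8, 1.1, 1.4, 1.8, 2.3]
        base = np.array([0.3, -0.5, 1.1, 2.2, -2.5, 0.2, 1.8, -0.7, 2.9, 0.4])
        results = [gbj_test(s * base, cm) for s in scales]
        stats = [r.statistic for r in results]
        ps = [r.p_value for r in results]
        assert all(b >= a for a, b in zip(stats, stats[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_floor_and_flag_for_extreme_evidence(self):
        z = np.full(10, 12.0)
        res = gbj_test(z, CorrMatrix.identity(10))
        assert res.p_value == 1e-12
        assert res.p_floored

    def test_calibration_at_one_percent(self, rng):
        """Rejection at the analytic 1% critical value over 4,000+ null
        draws stays inside the exact binomial 99% acceptance band."""
        from scipy.stats import binom as binom_dist

        reps = 4000
        lo, hi = binom_dist.ppf([0.005, 0.995], reps, 0.01) / reps
        for d in (5, 10, 20):
            for rho in (0.0, 0.3, 0.6):
                cm = CorrMatrix(exchangeable(d, rho)) if rho else CorrMatrix.identity(d)
                cv = gof_critical_value(0.01, d, cm, "gbj")
                L = np.linalg.cholesky(cm.sigma)
                Z = rng.standard_normal((reps, d)) @ L.T
                rej = float((gof_statistics_batch(Z, cm) > cv).mean())
                assert lo <= rej <= hi, f"d={d} rho={rho}: {rej}"


class TestComparators:
    def test_single_huge_signal_degenerate_case(self):
        z = np.zeros(10)
        z[3] = 6.5
        cm = CorrMatrix.identity(10)
        p_two = 2 * norm.sf(6.5)
        assert minp_test(z, cm).p_value == pytest.approx(p_two, abs=1e-6)
        assert ghc_test(z, cm).p_value == pytest.approx(p_two, abs=1e-6)

    def test_quadratic_identity_is_chi_square(self, rng):
        z = rng.standard_normal(10) * 1.3
        res = quadratic_test(z, CorrMatrix.identity(10))
        assert res.p_value == pytest.approx(chi2.sf(z @ z, 10), rel=1e-8)

    def test_quadratic_imhof_matches_mc(self, rng):
        d = 10
        sig = exchangeable(d, 0.3)
        z = rng.standard_normal(d) * 1.2
        res = quadratic_test(z, CorrMatrix(sig))
        L = np.linalg.cholesky(sig)
        Z = np.random.default_rng(271828).standard_normal((400_000, d)) @ L.T
        emp = float(((Z**2).sum(axis=1) >= z @ z).mean())
        se = np.sqrt(emp * (1 - emp) / 400_000)
        assert res.p_value == pytest.approx(emp, abs=3 * se)

    def test_minp_matches_mc_under_correlation(self, rng):
        d = 10
        sig = exchangeable(d, 0.3)
        z = rng.standard_normal(d)
        z[0] = 2.6
        res = minp_test(z, CorrMatrix(sig))
        L = np.linalg.cholesky(sig)
        Z = np.random.default_rng(161803).standard_normal((100_000, d)) @ L.T
        emp = float((np.abs(Z).max(axis=1) >= np.abs(z).max()).mean())
        se = np.sqrt(emp * (1 - emp) / 100_000)
        assert res.p_value == pytest.approx(emp, abs=3 * se)

    def test_minp_large_d_factor_path_matches_mc(self, rng):
        d = 40  # beyond the Genz cutoff
        sig = exchangeable(d, 0.3)
        z = rng.standard_normal(d)
        z[5] = 3.0
        res = minp_test(z, CorrMatrix(sig))
        L = np.linalg.cholesky(sig)
        Z = np.random.default_rng(141421).standard_normal((60_000, d)) @ L.T
        emp = float((np.abs(Z).max(axis=1) >= 3.0).mean())
        se = np.sqrt(emp * (1 - emp) / 60_000)
        assert res.p_value == pytest.approx(emp, abs=3 * se)

    def test_ghc_matches_mc_under_correlation(self, rng):
        d = 10
        sig = exchangeable(d, 0.3)
        cm = CorrMatrix(sig)
        z = rng.standard_normal(d)
        z[:2] = [2.4, -2.1]
        res = ghc_test(z, cm)
        L = np.linalg.cholesky(sig)
        stats = ghc_statistics_batch(
            np.random.default_rng(314159).standard_normal((400_000, d)) @ L.T, cm)
        emp = float((stats >= res.statistic - 1e-12).mean())
        se = np.sqrt(emp * (1 - emp) / 400_000)
        assert res.p_value == pytest.approx(emp, abs=3 * se)

    def test_comparator_map_keys(self, rng):
        z = rng.standard_normal(8)
        out = comparator_tests(z, CorrMatrix.identity(8))
        assert set(out) == {"ghc", "minp", "quadratic"}
        assert all(0 < p <= 1 for p in out.values())

    def test_single_z_pvalue(self):
        assert single_z_pvalue(1.959964) == pytest.approx(0.05, abs=1e-6)
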