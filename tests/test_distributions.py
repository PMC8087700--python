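"""Unit and property tests for the joint degree-feature distributions."""

import numpy as np
import pytest
from scipy import integrate, special, stats

import featperc as fp
from featperc.errors import DomainError


# ---------------------------------------------------------------------------
# independent family
# ---------------------------------------------------------------------------

class TestIndependent:
    def test_closed_form_values(self):
        d = fp.make_independent(0.5, 3.0)
        assert d.pk[0] == pytest.approx(0.5, abs=1e-12)
        # Pareto tail: P(F > 2) = 2^(1-3) * ... = 2^-2
        assert 1.0 - float(d.conditional_cdf(0, 2.0)) == pytest.approx(0.25)
        assert d.mean_degree == pytest.approx(1.0)

    def test_mean_degree_formula(self):
        for a in (0.3, 0.5, 0.7):
            d = fp.make_independent(a, 2.5)
            assert d.mean_degree == pytest.approx(a / (1 - a), rel=1e-12)
            assert float((d.k * d.pk).sum()) == pytest.approx(a / (1 - a),
                                                              rel=1e-9)

    @pytest.mark.parametrize("a,alpha", [(-0.1, 2.0), (0.0, 2.0), (1.0, 2.0),
                                         (0.5, 1.0), (0.5, 0.5)])
    def test_domain_errors(self, a, alpha):
        with pytest.raises(DomainError):
            fp.make_independent(a, alpha)

    def test_feature_independent_of_degree(self):
        d = fp.make_independent(0.4, 2.2)
        f = np.array([1.5, 3.0, 10.0])
        c0 = d.conditional_cdf(0, f)
        c7 = d.conditional_cdf(7, f)
        np.testing.assert_allclose(c0, c7)

    def test_conditional_mean_degree_constant(self):
        d = fp.make_independent(0.5, 3.0)
        vals = [fp.conditional_mean_degree(d, f) for f in (1.0, 2.0, 17.0)]
        np.testing.assert_allclose(vals, d.mean_degree, rtol=1e-9)


# ---------------------------------------------------------------------------
# positively correlated family
# ---------------------------------------------------------------------------

class TestPositive:
    def test_normalization_constant(self):
        import mpmath
        d = fp.make_positive(2.0)
        z_oracle = float((1 + 2) / (mpmath.zeta(3) - 1))
        assert d.Z == pytest.approx(z_oracle, rel=1e-12)
        assert d.Z == pytest.approx(14.8476, abs=5e-4)

    def test_degree_marginal_from_feature_integral(self):
        # p_k must equal the analytic integral of P(k,F) over F
        d = fp.make_positive(2.0)
        assert d.pk[0] == pytest.approx(0.6186, abs=5e-5)
        for i, k in enumerate([1, 2, 5, 11]):
            num, _ = integrate.quad(lambda f: d.Z * (k + f) ** (-4.0), 1,
                                    np.inf)
            assert d.pk[k - 1] == pytest.approx(num, rel=1e-9), k

    def test_conditional_mean_degree_nondecreasing(self):
        d = fp.make_positive(2.0)
        grid = [1.0, 2.0, 5.0, 10.0, 30.0]
        vals = [fp.conditional_mean_degree(d, f) for f in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert fp.conditional_mean_degree(d, 10.0) > \
            fp.conditional_mean_degree(d, 1.0)

    def test_conditional_mean_degree_oracle(self):
        # direct summation of k (k+F)^-(2+alpha), independent of the class
        alpha = 2.0
        d = fp.make_positive(alpha)
        for f in (1.0, 10.0):
            k = np.arange(1, 400_000, dtype=float)
            w = (k + f) ** (-(2 + alpha))
            oracle = (k * w).sum() / w.sum()
            assert fp.conditional_mean_degree(d, f) == pytest.approx(
                oracle, rel=1e-4)

    def test_alpha_domain(self):
        with pytest.raises(DomainError):
            fp.make_positive(1.0)


class TestNegative:
    def test_normalization_sum_oracle(self):
        # sum_{k>=1} 1/(k (k+1)^2) telescopes to 2 - pi^2/6
        d = fp.make_negative(2.0)
        assert d.norm_sum == pytest.approx(2.0 - np.pi ** 2 / 6.0, rel=1e-12)
        assert d.norm_sum == pytest.approx(0.3551, abs=5e-5)
        assert d.Z == pytest.approx(2.0 / 0.35506593315177, rel=1e-10)

    def test_direct_summation_oracle(self):
        alpha = 3.0
        d = fp.make_negative(alpha)
        k = np.arange(1, 2_000_000, dtype=float)
        oracle = float(np.sum(1.0 / (k * (k + 1) ** alpha)))
        assert d.norm_sum == pytest.approx(oracle, rel=1e-10)

    def test_conditional_mean_degree_nonincreasing(self):
        d = fp.make_negative(2.0)
        grid = [1.0, 2.0, 5.0, 10.0]
        vals = [fp.conditional_mean_degree(d, f) for f in grid]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert fp.conditional_mean_degree(d, 10.0) < \
            fp.conditional_mean_degree(d, 1.0)

    def test_alpha_domain(self):
        with pytest.raises(DomainError):
            fp.make_negative(0.9)


# ---------------------------------------------------------------------------
# TYPE invariants across the parameter grid
# ---------------------------------------------------------------------------

def _families_grid():
    for alpha in (1.5, 2.0, 3.0):
        yield fp.make_positive(alpha)
        yield fp.make_negative(alpha)
        for a in (0.3, 0.5, 0.7):
            yield fp.make_independent(a, alpha + 0.5)


@pytest.mark.parametrize("dist", list(_families_grid()),
                         ids=lambda d: f"{d.family}-{d.params}")
class TestTypeInvariants:
    def test_total_mass(self, dist):
        assert float(dist.pk.sum()) == pytest.approx(1.0, abs=1e-8)

    @staticmethod
    def _integrate_over_support(fn, support, scale=1.0):
        lo, hi = support
        if np.isinf(hi):
            # split at the conditional scale; map the tail to (0, 1]
            mid = lo + max(scale, 1.0)
            head, _ = integrate.quad(fn, lo, mid, limit=200)
            tail, _ = integrate.quad(
                lambda t: fn(mid / t) * mid / t ** 2, 0.0, 1.0, limit=200)
            return head + tail
        val, _ = integrate.quad(fn, lo, hi, limit=200)
        return val

    def test_marginal_consistency(self, dist):
        # integral of the conditional density recovers 1 for every probed k
        for k in dist.k[:: max(1, dist.k.size // 7)][:8]:
            scale = float(dist.conditional_ppf(int(k), 0.75))
            val = self._integrate_over_support(
                lambda f: float(dist.conditional_pdf(int(k), f)),
                dist.feature_support, scale=scale)
            assert val == pytest.approx(1.0, abs=1e-8), k

    def test_pk_equals_joint_integrated(self, dist):
        for k in dist.k[:6]:
            scale = float(dist.conditional_ppf(int(k), 0.75))
            val = self._integrate_over_support(
                lambda f: float(dist.joint_pdf(int(k), f)),
                dist.feature_support, scale=scale)
            assert val == pytest.approx(float(dist.pk[k == dist.k][0]),
                                        abs=1e-10), k

    def test_cdf_ppf_roundtrip(self, dist):
        q = np.linspace(0.01, 0.99, 21)
        for k in dist.k[:4]:
            f = np.asarray(dist.conditional_ppf(int(k), q), dtype=float)
            back = np.asarray(dist.conditional_cdf(int(k), f), dtype=float)
            np.testing.assert_allclose(back, q, atol=1e-9)

    def test_samples_in_support(self, dist):
        ks, fs = fp.sample_pairs(dist, 2000, seed=7)
        lo, hi = dist.feature_support
        assert fs.min() >= lo and fs.max() <= hi
        assert set(np.unique(ks)) <= set(dist.k.tolist())

    def test_mean_degree_vs_truncated_sum(self, dist):
        trunc = float((dist.k * dist.pk).sum())
        assert trunc <= dist.mean_degree + 1e-9
        # truncation error of sum k p_k is bounded by k_max * tail mass
        # plus the residual of the k^(1-alpha)-type tail: use the integral
        # bound sum_{k>K} k p_k <= K^(1-alpha)/(alpha-1) * scale
        alpha = dist.params.get("alpha")
        if dist.family == "independent":
            bound = 1e-9
        else:
            K = float(dist.k[-1])
            norm = (special.zeta(1.0 + alpha) - 1.0) \
                if dist.family == "positive" else dist.norm_sum
            bound = 2.0 * K ** (1.0 - alpha) / ((alpha - 1.0) * norm)
        assert dist.mean_degree - trunc <= bound + 1e-9


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_degree_histogram_matches_marginal(self):
        d = fp.make_independent(0.5, 3.0)
        ks, _ = fp.sample_pairs(d, 100_000, seed=3)
        kmax = 12
        obs = np.bincount(np.minimum(ks, kmax), minlength=kmax + 1)
        exp = np.append(d.pk[:kmax], 1.0 - d.pk[:kmax].sum()) * ks.size
        chi2 = stats.chisquare(obs, exp)
        assert chi2.pvalue > 1e-4

    def test_determinism(self, positive_dist):
        a = fp.sample_pairs(positive_dist, 500, seed=11)
        b = fp.sample_pairs(positive_dist, 500, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_positive_features_above_one(self, positive_dist):
        _, fs = fp.sample_pairs(positive_dist, 5000, seed=1)
        assert fs.min() >= 1.0

    def test_n_precondition(self, independent_dist):
        with pytest.raises(DomainError):
            fp.sample_pairs(independent_dist, 0, seed=1)

    def test_rank_correlation_signs(self):
        n = 100_000
        kp, fpos = fp.sample_pairs(fp.make_positive(2.0), n, seed=5)
        kn, fneg = fp.sample_pairs(fp.make_negative(2.0), n, seed=5)
        assert stats.spearmanr(kp, fpos).statistic > 0.1
        assert stats.spearmanr(kn, fneg).statistic < -0.1

    def test_shuffled_product_kills_correlation(self):
        base = fp.make_positive(2.0)
        prod = fp.shuffled_product(base)
        ks, fs = fp.sample_pairs(prod, 100_000, seed=9)
        assert abs(stats.spearmanr(ks, fs).statistic) < 0.01
        # degree marginal preserved exactly
        np.testing.assert_allclose(prod.pk, base.pk)
        # feature marginal preserved: KS against the analytic marginal CDF
        probe = np.quantile(fs, np.linspace(0.05, 0.95, 10))
        for f in probe:
            assert base.feature_marginal_mass_below(f) == pytest.approx(
                np.mean(fs < f), abs=0.01)


# ---------------------------------------------------------------------------
# feature support / domain errors
# ---------------------------------------------------------------------------

def test_conditional_mean_degree_outside_support(independent_dist):
    with pytest.raises(DomainError):
        fp.conditional_mean_degree(independent_dist, 0.5)


def test_spec_roundtrip(independent_dist):
    d2 = fp.from_spec(independent_dist.to_json())
    assert d2.params == independent_dist.params
    np.testing.assert_allclose(d2.pk, independent_dist.pk)


# ---------------------------------------------------------------------------
# discrete-feature mode and custom distributions
# ---------------------------------------------------------------------------

class TestDiscreteAndCustom:
    def test_discrete_threshold_convention(self):
        # feature masses at F in {1, 2, 3}; theta(0)=1 removal at F0=2
        mass = np.array([[0.2, 0.2, 0.1],
                         [0.1, 0.2, 0.2]])
        d = fp.DiscreteFeatureJoint([1, 2], [1.0, 2.0, 3.0], mass)
        # P(F < 2 | k=1) = 0.2/0.5
        assert float(d.mass_below(1, 2.0)) == pytest.approx(0.4)
        # P(F <= 2 | k=1) includes the atom at 2
        assert float(d.conditional_cdf(1, 2.0)) == pytest.approx(0.8)
        assert float(d.mass_at_or_above(1, 2.0)) == pytest.approx(0.6)

    def test_discrete_sampler_support(self):
        mass = np.ones((3, 4))
        d = fp.DiscreteFeatureJoint([1, 2, 3], [0.0, 0.5, 1.0, 1.5], mass)
        ks, fs = d.sample(500, seed=2)
        assert set(np.unique(fs)) <= {0.0, 0.5, 1.0, 1.5}

    def test_custom_from_callables_validates(self):
        good = fp.CustomJoint(
            np.arange(0, 30), 0.5 ** np.arange(1, 31),
            conditional_cdf=lambda k, f: 1 - np.exp(-np.asarray(f)),
            conditional_ppf=lambda k, q: -np.log1p(-np.asarray(q)),
            feature_support=(0.0, np.inf))
        assert good.pk.sum() == pytest.approx(1.0)
        with pytest.raises(DomainError):
            fp.CustomJoint(
                np.arange(0, 5), np.ones(5),
                conditional_cdf=lambda k, f: np.asarray(f) * 2.0,  # not a CDF
                conditional_ppf=lambda k, q: np.asarray(q),
                feature_support=(0.0, 1.0))

    def test_truncation_cap_error(self):
        import featperc.distributions as fd
        old = fd.TAIL_HARD_LIMIT
        try:
            fd.TAIL_HARD_LIMIT = 1e-16  # force the cap to be insufficient
            with pytest.raises(fp.TruncationError):
                fp.make_negative(1.2)
        finally:
            fd.TAIL_HARD_LIMIT = old
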