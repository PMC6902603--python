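"""Log posterior, analytic gradients and the unconstrained reparameterization."""

import numpy as np
import pytest
import scipy.stats

import bayesam as bs
from bayesam.model import (
    ParameterState,
    _unconstrained_logp_grad,
    from_unconstrained,
    grad_log_posterior,
    log_posterior,
    to_unconstrained,
)

from conftest import random_pedigree


def small_instance(n_animals, seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n_animals, rng)
    factor = bs.RelationshipFactor.from_pedigree(ped)
    X = np.column_stack([np.ones(n_animals), rng.integers(0, 2, n_animals)])
    a = factor.L @ rng.normal(size=n_animals)
    y = X @ np.array([1.0, -0.5]) + a + rng.normal(size=n_animals) * 0.7
    data = bs.ModelData(
        y=y,
        X=X,
        rec_animal=np.arange(n_animals),
        q=n_animals,
        fixed_names=("intercept", "grp"),
    )
    return data, factor, rng


def random_state(data, factor, rng):
    return ParameterState(
        b=rng.normal(size=data.p),
        a=factor.L @ rng.normal(size=data.q),
        sigma2_a=float(rng.uniform(0.2, 2.0)),
        sigma2_e=float(rng.uniform(0.2, 2.0)),
    )


class TestLogPosterior:
    def test_difference_matches_direct_gaussian_densities(self):
        """log f(theta1) - log f(theta2) equals the difference computed from
        the two multivariate normal density formulas directly."""
        data, factor, rng = small_instance(5, 1)
        s1, s2 = random_state(data, factor, rng), random_state(data, factor, rng)

        def direct(s):
            like = scipy.stats.multivariate_normal.logpdf(
                data.y,
                data.X @ s.b + data.z_matrix() @ s.a,
                np.eye(data.n) * s.sigma2_e,
            )
            prior = scipy.stats.multivariate_normal.logpdf(
                s.a, np.zeros(data.q), factor.A * s.sigma2_a
            )
            return like + prior

        mine = log_posterior(s1, data, factor) - log_posterior(s2, data, factor)
        assert mine == pytest.approx(direct(s1) - direct(s2), rel=1e-9)

    def test_translation_invariance(self):
        """Adding c to y and to the intercept leaves log f unchanged."""
        data, factor, rng = small_instance(6, 2)
        s = random_state(data, factor, rng)
        shifted = bs.ModelData(
            y=data.y + 3.7,
            X=data.X,
            rec_animal=data.rec_animal,
            q=data.q,
            fixed_names=data.fixed_names,
        )
        s_shift = ParameterState(
            b=s.b + np.array([3.7, 0.0]),
            a=s.a,
            sigma2_a=s.sigma2_a,
            sigma2_e=s.sigma2_e,
        )
        assert log_posterior(s, data, factor) == pytest.approx(
            log_posterior(s_shift, shifted, factor), rel=1e-12
        )

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(bs.model.DomainError):
            ParameterState(
                b=np.zeros(1), a=np.zeros(2), sigma2_a=-1.0, sigma2_e=1.0
            )


class TestGradients:
    def test_zero_residual_zeroes_data_terms(self):
        data, factor, rng = small_instance(5, 3)
        s = random_state(data, factor, rng)
        y_exact = data.X @ s.b + s.a[data.rec_animal]
        exact = bs.ModelData(
            y=y_exact, X=data.X, rec_animal=data.rec_animal, q=data.q
        )
        g = grad_log_posterior(s, exact, factor)
        np.testing.assert_allclose(g.b, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            g.a, -factor.solve_a_inverse(s.a) / s.sigma2_a, atol=1e-10
        )

    def test_sigma2_a_stationary_point(self):
        data, factor, rng = small_instance(5, 4)
        s = random_state(data, factor, rng)
        ainv_a = factor.solve_a_inverse(s.a)
        s_star = ParameterState(
            b=s.b, a=s.a, sigma2_a=float(s.a @ ainv_a) / data.q, sigma2_e=s.sigma2_e
        )
        assert grad_log_posterior(s_star, data, factor).sigma2_a == pytest.approx(
            0.0, abs=1e-10
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_constrained_gradient_matches_finite_differences(self, seed):
        data, factor, rng = small_instance(8, seed + 10)
        s = random_state(data, factor, rng)
        g = grad_log_posterior(s, data, factor)
        flat = np.concatenate([g.b, g.a, [g.sigma2_a], [g.sigma2_e]])

        def f(vec):
            return log_posterior(
                ParameterState(
                    b=vec[: data.p],
                    a=vec[data.p : data.p + data.q],
                    sigma2_a=vec[-2],
                    sigma2_e=vec[-1],
                ),
                data,
                factor,
            )

        x0 = np.concatenate([s.b, s.a, [s.sigma2_a], [s.sigma2_e]])
        num = np.array(
            [
                (f(x0 + h * np.eye(len(x0))[i]) - f(x0 - h * np.eye(len(x0))[i]))
                / (2 * h)
                for i, h in [(i, 1e-6) for i in range(len(x0))]
            ]
        )
        np.testing.assert_allclose(flat, num, rtol=1e-6, atol=1e-6)


class TestUnconstrained:
    def test_round_trip_identity(self):
        data, factor, rng = small_instance(7, 5)
        s = random_state(data, factor, rng)
        theta = to_unconstrained(s, factor)
        back = from_unconstrained(theta, data.p, factor)
        np.testing.assert_allclose(back.b, s.b, atol=1e-12)
        np.testing.assert_allclose(back.a, s.a, atol=1e-12)
        assert back.sigma2_a == pytest.approx(s.sigma2_a, rel=1e-12)
        assert back.sigma2_e == pytest.approx(s.sigma2_e, rel=1e-12)

    def test_zero_u_gives_zero_a(self):
        data, factor, _ = small_instance(5, 6)
        theta = np.zeros(data.p + data.q + 2)
        assert np.all(from_unconstrained(theta, data.p, factor).a == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unconstrained_gradient_matches_finite_differences(self, seed):
        data, factor, rng = small_instance(8, seed + 20)
        theta = rng.normal(size=data.p + data.q + 2) * 0.5
        _, grad = _unconstrained_logp_grad(theta, data, factor)
        num = np.empty_like(theta)
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            num[i] = (
                _unconstrained_logp_grad(theta + e, data, factor)[0]
                - _unconstrained_logp_grad(theta - e, data, factor)[0]
            ) / 2e-6
        np.testing.assert_allclose(grad, num, rtol=1e-6, atol=1e-5)

    def test_chain_rule_log_variance(self):
        """d/dlog s2e = s2e * d/ds2e + 1 (the +1 is the Jacobian term).

        Holds for the residual variance, whose coordinate is a plain log
        transform; the genetic variance also rescales u, so its
        unconstrained gradient is covered by the finite-difference check.
        """
        data, factor, rng = small_instance(6, 7)
        s = random_state(data, factor, rng)
        g_con = grad_log_posterior(s, data, factor)
        theta = to_unconstrained(s, factor)
        _, g_unc = _unconstrained_logp_grad(theta, data, factor)
        assert g_unc[-1] == pytest.approx(s.sigma2_e * g_con.sigma2_e + 1.0, rel=1e-8)

    def test_fast_target_matches_reference_implementation(self):
        """The BLAS-trmv target used by the samplers returns exactly the
        same density and gradient as the plain-numpy reference."""
        from bayesam.model import make_target

        data, factor, rng = small_instance(10, 9)
        target = make_target(data, factor)
        for _ in range(5):
            theta = rng.normal(size=data.p + data.q + 2) * 0.6
            lp_fast, g_fast = target(theta)
            lp_ref, g_ref = _unconstrained_logp_grad(theta, data, factor)
            assert lp_fast == pytest.approx(lp_ref, rel=1e-12, abs=1e-9)
            np.testing.assert_allclose(g_fast, g_ref, rtol=1e-10, atol=1e-10)

    def test_whitened_prior_equivalence(self):
        """log N(a|0, A s2a) + log|L| = log N(u|0, I s2a) when a = L u."""
        data, factor, rng = small_instance(6, 8)
        s = random_state(data, factor, rng)
        u = factor.whiten(s.a)
        lhs = scipy.stats.multivariate_normal.logpdf(
            s.a, np.zeros(data.q), factor.A * s.sigma2_a
        ) + np.sum(np.log(np.diag(factor.L)))
        rhs = scipy.stats.norm.logpdf(u, 0.0, np.sqrt(s.sigma2_a)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)
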