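"""No-U-Turn Sampler: slice draws, U-turn rule, doubling, dual averaging."""

import numpy as np
import pytest
import scipy.stats

import bayesam as bs
from bayesam.hmc import kinetic_energy
from bayesam.nuts import (
    DualAveragingState,
    NUTSConfig,
    _Node,
    accept_statistic,
    build_tree,
    draw_slice,
    dual_averaging_update,
    find_reasonable_epsilon,
    nuts_sample,
    transition_select,
    uturn_stop,
)


def std_normal_target(theta):
    return -0.5 * float(theta @ theta), -theta


class TestDrawSlice:
    def test_log_u_never_exceeds_joint(self, rng):
        joint = -3.2
        for _ in range(100):
            assert draw_slice(joint, rng) <= joint

    def test_ratio_uniform(self, rng):
        """u / exp(joint) is U(0,1)."""
        joint = -5.0
        ratios = np.exp([draw_slice(joint, rng) - joint for _ in range(100_000)])
        assert scipy.stats.kstest(ratios, "uniform").pvalue > 0.01

    def test_log_scale_matches_direct_scale(self, rng):
        """Where exp(joint) does not underflow the log-scale draw is the
        same transform of the same uniform."""
        joint = -2.0
        state = rng.bit_generator.state
        log_u = draw_slice(joint, rng)
        rng.bit_generator.state = state
        u_direct = np.exp(joint) * rng.uniform()
        assert log_u == pytest.approx(np.log(u_direct), rel=1e-12)


class TestUTurn:
    def test_coincident_endpoints_no_stop(self):
        th = np.array([0.3, -0.2])
        p = np.array([1.0, 0.5])
        assert not uturn_stop(th, th, p, p)

    def test_aligned_momenta_no_stop(self):
        assert not uturn_stop(
            np.array([1.0, 0.0]), np.array([0.0, 0.0]),
            np.array([1.0, 0.0]), np.array([1.0, 0.0]),
        )

    def test_reversed_momentum_stops(self):
        assert uturn_stop(
            np.array([1.0, 0.0]), np.array([0.0, 0.0]),
            np.array([1.0, 0.0]), np.array([-1.0, 0.0]),
        )


class TestTransitionSelect:
    def test_empty_new_subtree_keeps_old(self, rng):
        assert not transition_select(5, 0, rng)

    def test_larger_new_subtree_always_selected(self, rng):
        assert transition_select(3, 3, rng) and transition_select(1, 8, rng)

    def test_half_probability_frequency(self):
        rng = np.random.default_rng(0)
        hits = sum(transition_select(2, 1, rng) for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(0.5, abs=0.005)


class TestAcceptStatistic:
    def test_constant_ratio_values(self):
        node = _Node(np.zeros(1), np.zeros(1), 0.0, np.zeros(1))

        def tree(alpha_sum, n):
            return bs.nuts.TreeState(
                minus=node, plus=node, proposal=node, proposal_joint=0.0,
                n_valid=n, stop=False, alpha_sum=alpha_sum, n_alpha=n,
            )

        assert accept_statistic(tree(4.0, 4)) == 1.0
        assert accept_statistic(tree(3 * np.exp(-1.0), 3)) == pytest.approx(
            np.exp(-1.0)
        )
        assert accept_statistic(tree(0.5, 1)) == 0.5


class TestBuildTree:
    def make_leaf_args(self, rng):
        theta = np.array([0.1, -0.3])
        logp, grad = std_normal_target(theta)
        p = rng.normal(size=2)
        joint0 = logp - kinetic_energy(p)
        return _Node(theta, p, logp, grad), joint0

    def test_depth0_valid_state_counted(self, rng):
        node, joint0 = self.make_leaf_args(rng)
        tree = build_tree(
            std_normal_target, node, joint0 - 10.0, 1, 0, 0.1, joint0, rng
        )
        assert tree.n_valid == 1 and not tree.stop

    def test_cardinality_bound(self, rng):
        node, joint0 = self.make_leaf_args(rng)
        for depth in range(5):
            tree = build_tree(
                std_normal_target, node, joint0 - 10.0, 1, depth, 0.05, joint0, rng
            )
            assert 0 <= tree.n_valid <= 2**depth

    def test_divergent_leaf_stops(self, rng):
        node, joint0 = self.make_leaf_args(rng)
        # log_u far above any reachable joint density -> catastrophic violation
        tree = build_tree(
            std_normal_target, node, joint0 + 2000.0, 1, 0, 0.1, joint0, rng
        )
        assert tree.stop and tree.divergent and tree.n_valid == 0


class TestDualAveraging:
    def test_alpha_equal_delta_keeps_mu(self):
        da = DualAveragingState(mu=np.log(0.7), log_eps=np.log(0.7), delta=0.6)
        for _ in range(50):
            da = dual_averaging_update(da, 0.6)
            assert da.log_eps == pytest.approx(da.mu)

    def test_zero_acceptance_shrinks_epsilon(self):
        da = DualAveragingState(mu=np.log(1.0), log_eps=0.0, delta=0.6)
        eps_values = []
        for _ in range(30):
            da = dual_averaging_update(da, 0.0)
            eps_values.append(da.epsilon)
        assert all(b < a for a, b in zip(eps_values, eps_values[1:]))

    def test_adaptation_reaches_target_on_gaussian(self):
        rng = np.random.default_rng(11)
        out = nuts_sample(
            std_normal_target, rng.normal(size=10), 2000, 1000, rng, delta=0.6
        )
        post_alpha = out["alphas"][1000:].mean()
        assert abs(post_alpha - 0.6) < 0.1


class TestNutsSampling:
    def test_standard_normal_marginal_ks(self):
        """Draws from a 1-d standard normal target follow N(0,1)."""
        rng = np.random.default_rng(21)
        out = nuts_sample(
            std_normal_target, np.array([1.5]), 22_000, 2000, rng, delta=0.6
        )
        x = out["thetas"][:, 0]
        # thin to near-independence before the KS test
        assert scipy.stats.kstest(x[::10], "norm").pvalue > 0.01

    def test_correlated_gaussian_covariance_recovery(self):
        """2-d Gaussian with rho = 0.9: posterior covariance within 5%."""
        rho = 0.9
        cov = np.array([[1.0, rho], [rho, 1.0]])
        prec = np.linalg.inv(cov)

        def target(theta):
            return -0.5 * float(theta @ prec @ theta), -(prec @ theta)

        rng = np.random.default_rng(8)
        out = nuts_sample(target, np.zeros(2), 32_000, 2000, rng, delta=0.6)
        emp = np.cov(out["thetas"].T)
        assert np.all(np.abs(emp - cov) < 0.05)

    def test_slice_condition_never_violated(self):
        rng = np.random.default_rng(4)
        out = nuts_sample(std_normal_target, np.ones(5), 3000, 500, rng)
        assert out["n_slice_violations"] == 0

    def test_find_reasonable_epsilon_order_of_magnitude(self):
        rng = np.random.default_rng(2)
        eps = find_reasonable_epsilon(std_normal_target, np.zeros(5), rng)
        assert 0.05 < eps < 20.0


class TestNutsRun:
    @pytest.mark.filterwarnings("ignore:NUTS.*divergent:RuntimeWarning")
    def test_store_and_meta(self, tiny_sim):
        # the tiny dataset identifies h2 weakly (a mild funnel), so some
        # divergent iterations are expected and allowed here
        sim, data = tiny_sim
        store = bs.nuts_run(
            data, sim.factor, NUTSConfig(n_iter=800, warmup=300, seed=9)
        )
        assert len(store) == 500
        h2 = store.draws.h2.to_numpy()
        assert ((h2 > 0) & (h2 < 1)).all()
        assert store.meta["epsilon"] > 0
        assert store.meta["n_slice_violations"] == 0
        assert len(store.meta["eps_trace"]) == 300

    def test_agrees_with_gibbs_on_small_data(self, tiny_sim):
        sim, data = tiny_sim
        nuts = bs.nuts_run(
            data, sim.factor, NUTSConfig(n_iter=3000, warmup=1000, seed=13)
        )
        gibbs = bs.gibbs_run(
            data, sim.factor, bs.GibbsConfig(n_iter=12_000, burn_in=2000, seed=13)
        )
        assert abs(nuts.draws.h2.mean() - gibbs.draws.h2.mean()) < 0.05
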