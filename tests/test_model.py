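import numpy as np
import pytest
from scipy import stats

from regmis import (
    BetaPrior,
    GammaPrior,
    ModelConfig,
    PairData,
    PairMisclassificationModel,
    gibbs_run,
    oracle_posterior,
    summarize,
)
from regmis.model import (
    Chain,
    crude_rate_prior,
    lambda_conditionals,
    theta_conditional,
    z_conditional,
)


class TestPairData:
    def test_validation(self):
        with pytest.raises(ValueError):
            PairData(y_S=[1], y_R=[1, 2], n_S=[1.0], n_R=[1.0])
        with pytest.raises(ValueError):
            PairData(y_S=[-1], y_R=[0], n_S=[1.0], n_R=[1.0])
        with pytest.raises(ValueError):
            PairData(y_S=[1.5], y_R=[0], n_S=[1.0], n_R=[1.0])
        with pytest.raises(ValueError):
            PairData(y_S=[1], y_R=[0], n_S=[0.0], n_R=[1.0])


class TestConditionals:
    """Closed forms of the three full conditionals."""

    @pytest.mark.parametrize(
        "theta,lamS_nS,lamR_nR,p",
        [
            (0.0, 5.0, 5.0, 0.0),
            (0.7, 5.0, 0.0, 1.0),
            (0.5, 4.0, 4.0, 1.0 / 3.0),
        ],
    )
    def test_z_success_probability(self, theta, lamS_nS, lamR_nR, p):
        trials, prob = z_conditional(6, theta, lamS_nS, lamR_nR)
        assert trials == 6
        assert prob == pytest.approx(p)

    def test_z_degenerate_rejected(self):
        with pytest.raises(ZeroDivisionError):
            z_conditional(3, 0.0, 0.0, 0.0)

    def test_theta_conjugate_update(self):
        post = theta_conditional(3, 7, BetaPrior(1, 1))
        assert (post.a, post.b) == (4.0, 8.0)
        assert post.mean == pytest.approx(1.0 / 3.0)
        # no data: posterior equals prior
        prior = BetaPrior(46.10, 53.90)
        assert theta_conditional(0, 0, prior).mean == pytest.approx(0.4610)

    def test_lambda_updates(self):
        prior = GammaPrior(1.0, 1e-9)  # near-improper limit
        sender, receiver = lambda_conditionals(2, 1, 4, 100.0, 100.0, prior)
        assert sender.mean == pytest.approx((1 + 2 + 1) / 100.0, rel=1e-6)
        assert receiver.mean == pytest.approx((1 + 4 - 1) / 100.0, rel=1e-6)
        with pytest.raises(ValueError):
            lambda_conditionals(2, 5, 4, 100.0, 100.0, prior)


class TestConditionalsMatchJoint:
    """Each full conditional is proportional to the joint density in its block."""

    @staticmethod
    def _log_joint(pair, theta, lam_S, lam_R, z, tp, rp):
        T = pair.y_S + z
        W = pair.y_R - z
        lp = stats.beta.logpdf(theta, tp.a, tp.b)
        lp += stats.gamma.logpdf(lam_S, rp.shape, scale=1 / rp.rate).sum()
        lp += stats.gamma.logpdf(lam_R, rp.shape, scale=1 / rp.rate).sum()
        lp += stats.poisson.logpmf(T, lam_S * pair.n_S).sum()
        lp += stats.binom.logpmf(z, T, theta).sum()
        lp += stats.poisson.logpmf(W, lam_R * pair.n_R).sum()
        return lp

    @pytest.fixture
    def state(self, toy_pair, toy_prior, toy_rate_prior):
        rng = np.random.default_rng(5)
        z = rng.integers(0, toy_pair.y_R + 1).astype(float)
        lam_S = rng.gamma(2.0, 0.002, size=2)
        lam_R = rng.gamma(2.0, 0.002, size=2)
        return toy_pair, toy_prior, toy_rate_prior, z, lam_S, lam_R

    def test_theta_block(self, state):
        pair, tp, rp, z, lam_S, lam_R = state
        post = theta_conditional(z.sum(), pair.y_S.sum(), tp)
        for t1, t2 in [(0.2, 0.7), (0.35, 0.9)]:
            joint = self._log_joint(pair, t1, lam_S, lam_R, z, tp, rp) - self._log_joint(
                pair, t2, lam_S, lam_R, z, tp, rp
            )
            cond = stats.beta.logpdf(t1, post.a, post.b) - stats.beta.logpdf(
                t2, post.a, post.b
            )
            assert joint == pytest.approx(cond, abs=1e-9)

    def test_lambda_block(self, state):
        pair, tp, rp, z, lam_S, lam_R = state
        j = 0
        send, recv = lambda_conditionals(
            pair.y_S[j], z[j], pair.y_R[j], pair.n_S[j], pair.n_R[j], rp
        )
        for l1, l2 in [(0.001, 0.004), (0.0005, 0.01)]:
            a = lam_S.copy(); a[j] = l1
            b = lam_S.copy(); b[j] = l2
            joint = self._log_joint(pair, 0.3, a, lam_R, z, tp, rp) - self._log_joint(
                pair, 0.3, b, lam_R, z, tp, rp
            )
            cond = stats.gamma.logpdf(l1, send.shape, scale=1 / send.rate) - stats.gamma.logpdf(
                l2, send.shape, scale=1 / send.rate
            )
            assert joint == pytest.approx(cond, abs=1e-9)

    def test_z_block(self, state):
        pair, tp, rp, z, lam_S, lam_R = state
        theta = 0.4
        j = 1
        trials, p = z_conditional(
            pair.y_R[j], theta, lam_S[j] * pair.n_S[j], lam_R[j] * pair.n_R[j]
        )
        for z1, z2 in [(0, 3), (1, 4)]:
            a = z.copy(); a[j] = z1
            b = z.copy(); b[j] = z2
            joint = self._log_joint(pair, theta, lam_S, lam_R, a, tp, rp) - self._log_joint(
                pair, theta, lam_S, lam_R, b, tp, rp
            )
            cond = stats.binom.logpmf(z1, trials, p) - stats.binom.logpmf(z2, trials, p)
            assert joint == pytest.approx(cond, abs=1e-9)


class TestOracle:
    def test_zero_counts_recovers_prior_mean(self, zero_pair):
        prior = BetaPrior(46.10, 53.90)
        orc = oracle_posterior(zero_pair, prior, GammaPrior(1.0, 100.0), grid_size=4001)
        assert orc.theta_mean == pytest.approx(prior.mean, abs=1e-4)
        assert np.all(orc.z_mean == 0.0)

    def test_stratum_permutation_invariance(self):
        # theta is shared across strata, so permuting strata permutes
        # z_mean and leaves the theta posterior untouched
        rp = GammaPrior(1.0, 300.0)
        a = PairData(y_S=[3, 2], y_R=[4, 5], n_S=[1000, 2000], n_R=[1500, 1000])
        b = PairData(y_S=[2, 3], y_R=[5, 4], n_S=[2000, 1000], n_R=[1000, 1500])
        oa = oracle_posterior(a, BetaPrior(2, 3), rp, grid_size=2001)
        ob = oracle_posterior(b, BetaPrior(2, 3), rp, grid_size=2001)
        np.testing.assert_allclose(oa.density, ob.density, atol=1e-12)
        np.testing.assert_allclose(oa.z_mean, ob.z_mean[::-1], atol=1e-10)

    def test_enumeration_guard(self):
        big = PairData(
            y_S=np.zeros(8), y_R=np.full(8, 100.0), n_S=np.ones(8), n_R=np.ones(8)
        )
        with pytest.raises(ValueError, match="guard"):
            oracle_posterior(big, BetaPrior(1, 1), GammaPrior(1, 1))

    def test_density_normalized(self, toy_pair, toy_prior, toy_rate_prior):
        orc = oracle_posterior(toy_pair, toy_prior, toy_rate_prior)
        assert orc.density.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(orc.z_mean >= 0) and np.all(orc.z_mean <= toy_pair.y_R)


class TestGibbs:
    def test_bitwise_reproducible(self, toy_pair, toy_prior, toy_rate_prior):
        cfg = ModelConfig(iterations=1500, burn_in=500, seed=42)
        c1 = gibbs_run(toy_pair, toy_prior, toy_rate_prior, cfg)
        c2 = gibbs_run(toy_pair, toy_prior, toy_rate_prior, cfg)
        np.testing.assert_array_equal(c1.theta, c2.theta)
        np.testing.assert_array_equal(c1.z, c2.z)
        np.testing.assert_array_equal(c1.lambda_S, c2.lambda_S)

    def test_thinning_and_length(self, toy_pair, toy_prior, toy_rate_prior):
        cfg = ModelConfig(iterations=5000, burn_in=1000, thin=4, seed=0)
        chain = gibbs_run(toy_pair, toy_prior, toy_rate_prior, cfg)
        assert len(chain) == 1000

    def test_zero_counts_posterior_is_prior(self, zero_pair):
        prior = BetaPrior(46.10, 53.90)
        cfg = ModelConfig(iterations=6000, burn_in=1000, seed=3)
        s = summarize(gibbs_run(zero_pair, prior, GammaPrior(1.0, 100.0), cfg))
        assert abs(s.theta_mean - prior.mean) <= 3 * s.mcse_theta
        assert np.all(s.z_mean == 0.0)

    def test_matches_oracle_on_toy_pair(self, toy_pair, toy_prior, toy_rate_prior):
        orc = oracle_posterior(toy_pair, toy_prior, toy_rate_prior)
        cfg = ModelConfig(iterations=12_000, burn_in=2_000, seed=9)
        s = summarize(gibbs_run(toy_pair, toy_prior, toy_rate_prior, cfg))
        assert s.theta_mean == pytest.approx(orc.theta_mean, abs=0.02)
        np.testing.assert_allclose(s.z_mean, orc.z_mean, atol=0.1)

    def test_short_run_warns(self, toy_pair):
        with pytest.warns(UserWarning, match="burn-in"):
            ModelConfig(iterations=500, burn_in=100)

    def test_chain_bounds_invariants(self, toy_pair, toy_prior, toy_rate_prior):
        chain = gibbs_run(
            toy_pair, toy_prior, toy_rate_prior, ModelConfig(iterations=2000, burn_in=1000, seed=1)
        )
        assert np.all((chain.theta > 0) & (chain.theta < 1))
        assert np.all(chain.z >= 0) and np.all(chain.z <= toy_pair.y_R)
        assert np.all(chain.lambda_S > 0) and np.all(chain.lambda_R > 0)


class TestSummarize:
    def test_constant_chain(self):
        chain = Chain(
            theta=np.full(100, 0.3),
            z=np.zeros((100, 2)),
            lambda_S=np.ones((100, 2)),
            lambda_R=np.ones((100, 2)),
        )
        s = summarize(chain)
        assert s.theta_mean == 0.3
        assert s.theta_ci == (0.3, 0.3)
        assert s.theta_sd == 0.0

    def test_iid_beta_draws(self):
        rng = np.random.default_rng(0)
        theta = rng.beta(2, 2, size=20_000)
        chain = Chain(theta, np.zeros((theta.size, 1)), np.ones((theta.size, 1)), np.ones((theta.size, 1)))
        s = summarize(chain)
        assert abs(s.theta_mean - 0.5) <= 3 * s.mcse_theta

    def test_empty_chain_rejected(self):
        chain = Chain(np.array([]), np.zeros((0, 1)), np.zeros((0, 1)), np.zeros((0, 1)))
        with pytest.raises(ValueError):
            summarize(chain)


class TestIdentifiability:
    """Separate rates leave theta prior-dominated; shared rates identify it."""

    @staticmethod
    def _simulated_pair(theta_true, seed):
        rng = np.random.default_rng(seed)
        rates = np.array([30, 50, 80, 120, 150, 90, 60, 40], dtype=float) / 3e5
        n = np.full(8, 3e5)
        t = rng.poisson(rates * n)
        z = rng.binomial(t, theta_true)
        w = rng.poisson(rates * n)
        return PairData(y_S=(t - z).astype(float), y_R=(w + z).astype(float), n_S=n, n_R=n)

    def test_shared_rates_recover_theta_with_flat_prior(self):
        pair = self._simulated_pair(0.4, seed=21)
        est = PairMisclassificationModel(
            iterations=6000, burn_in=1000, shared_rates=True, random_state=4
        ).fit(pair)
        assert est.theta_mean_ == pytest.approx(0.4, abs=0.05)

    def test_separate_rates_follow_informative_prior(self):
        pair = self._simulated_pair(0.4, seed=21)
        for mean in (0.2, 0.7):
            est = PairMisclassificationModel(
                prior_a=100 * mean, prior_b=100 * (1 - mean),
                iterations=4000, burn_in=1000, shared_rates=False, random_state=4,
            ).fit(pair)
            # posterior mean tracks the prior mean, not theta_true
            assert abs(est.theta_mean_ - mean) < abs(est.theta_mean_ - 0.4) + 0.15


class TestEstimatorFacade:
    def test_sklearn_contract(self, toy_pair):
        est = PairMisclassificationModel(iterations=1500, burn_in=500)
        params = est.get_params()
        assert params["shared_rates"] is False
        est.set_params(random_state=7, iterations=2000).fit(toy_pair)
        assert 0 < est.theta_mean_ < 1
        assert est.theta_ci_[0] <= est.theta_mean_ <= est.theta_ci_[1]
        assert est.chain_.theta.shape == (1500,)

    def test_oracle_shortcut_matches_function(self, toy_pair):
        est = PairMisclassificationModel(prior_a=2, prior_b=2, rate_rate=300.0)
        orc = est.oracle(toy_pair, grid_size=1001)
        direct = oracle_posterior(
            toy_pair, BetaPrior(2, 2), GammaPrior(1.0, 300.0), grid_size=1001
        )
        assert orc.theta_mean == pytest.approx(direct.theta_mean, abs=1e-12)

    def test_rejects_non_pairdata(self):
        with pytest.raises(TypeError):
            PairMisclassificationModel().fit(np.zeros((4, 2)))
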