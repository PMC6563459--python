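from itertools import product

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from levelcast.spike_slab import (
    DegenerateDesignError,
    RegressionDraw,
    SSVSWorkspace,
    build_prior,
    draw_beta_sigma,
    gibbs_gamma_sweep,
    log_marginal,
    standardize_design,
)


def make_problem(seed=2, n=6, k=3, beta=(1.5, 0.0, 0.0), noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, k))
    z, _, _ = standardize_design(x)
    y = z @ np.asarray(beta) + rng.normal(0, noise, n)
    return z, y


def quadrature_log_marginal(gamma, z, y, prior):
    """Independent oracle: integrate beta analytically via a dense MVN
    density, then integrate sigma^2 numerically against its prior."""
    n = len(y)
    idx = np.flatnonzero(gamma)
    core = np.eye(n)
    if idx.size:
        xg = z[:, idx]
        og = prior.slab_information[np.ix_(idx, idx)]
        core = core + xg @ np.linalg.solve(og, xg.T)
    ig = sps.invgamma(
        a=prior.variance_prior_df / 2, scale=prior.variance_prior_sum_of_squares / 2
    )

    def integrand(s2):
        return np.exp(
            sps.multivariate_normal(mean=np.zeros(n), cov=s2 * core).logpdf(y)
        ) * ig.pdf(s2)

    val, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-14, epsrel=1e-12, limit=400)
    return np.log(val)


def enumeration_inclusion_probabilities(z, y, prior):
    """Exhaustive 2^K model average of the inclusion indicators."""
    k = z.shape[1]
    pi = prior.inclusion_prob
    log_w, gammas = [], []
    for gamma in product([0, 1], repeat=k):
        g = np.array(gamma)
        lp = np.sum(np.where(g == 1, np.log(pi), np.log1p(-pi)))
        log_w.append(log_marginal(g, y, z, prior) + lp)
        gammas.append(g)
    w = np.exp(np.array(log_w) - max(log_w))
    w /= w.sum()
    return (np.stack(gammas) * w[:, None]).sum(axis=0)


class TestBuildPrior:
    def test_inclusion_probability_is_expected_size_over_k(self, rng):
        z, y = make_problem(n=13, k=9, beta=np.zeros(9))
        prior = build_prior(z, y, expected_model_size=5, expected_rsq=0.7)
        assert np.allclose(prior.inclusion_prob, 5.0 / 9.0)

    def test_sum_of_squares_from_expected_rsq(self, rng):
        z, y = make_problem(n=13, k=9, beta=np.zeros(9))
        prior = build_prior(z, y, 5, expected_rsq=0.70, prior_df=12.0)
        assert prior.variance_prior_sum_of_squares == pytest.approx(
            12.0 * 0.30 * np.var(y, ddof=1)
        )

    def test_single_covariate_full_inclusion(self):
        z, y = make_problem(k=1, beta=(1.0,))
        prior = build_prior(z, y, expected_model_size=1, expected_rsq=0.5)
        assert prior.inclusion_prob[0] == 1.0

    def test_model_size_exceeding_k_rejected(self):
        z, y = make_problem()
        with pytest.raises(ValueError):
            build_prior(z, y, expected_model_size=5, expected_rsq=0.5)

    def test_zero_variance_covariate_named(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 2))
        x[:, 1] = 7.0
        with pytest.raises(DegenerateDesignError, match="pop_x"):
            build_prior(x, rng.normal(size=10), 1, 0.5, column_names=["a", "pop_x"])

    def test_slab_information_formula(self):
        z, y = make_problem(n=8, k=3)
        w, weight = 0.5, 2.0
        prior = build_prior(z, y, 2, 0.5, prior_obs_weight=weight, diagonal_shrinkage=w)
        xtx = z.T @ z
        expected = (weight / 8) * (w * xtx + (1 - w) * np.diag(np.diag(xtx)))
        assert np.allclose(prior.slab_information, expected)


class TestLogMarginal:
    def test_null_model_is_multivariate_t(self):
        z, y = make_problem()
        prior = build_prior(z, y, 2, 0.6, prior_obs_weight=1.0, prior_df=3.0)
        df, ss = prior.variance_prior_df, prior.variance_prior_sum_of_squares
        dense = sps.multivariate_t(
            loc=np.zeros(len(y)), shape=(ss / df) * np.eye(len(y)), df=df
        ).logpdf(y)
        assert log_marginal([0, 0, 0], y, z, prior) == pytest.approx(dense, abs=1e-10)

    def test_all_zero_covariate_with_isolated_slab_changes_nothing(self):
        z, y = make_problem(k=2, beta=(1.0, 0.0))
        z3 = np.column_stack([z, np.zeros(len(y))])
        omega = np.zeros((3, 3))
        omega[:2, :2] = (z.T @ z) / 2.0
        omega[2, 2] = 0.7  # isolated slab precision for the null column
        prior3 = type(build_prior(z, y, 1, 0.5))(
            inclusion_prob=np.full(3, 0.5),
            slab_mean=np.zeros(3),
            slab_information=omega,
            variance_prior_df=5.0,
            variance_prior_sum_of_squares=2.0,
        )
        prior2 = type(prior3)(
            inclusion_prob=np.full(2, 0.5),
            slab_mean=np.zeros(2),
            slab_information=omega[:2, :2],
            variance_prior_df=5.0,
            variance_prior_sum_of_squares=2.0,
        )
        with_null = log_marginal([1, 0, 1], y, z3, prior3)
        without = log_marginal([1, 0], y, z, prior2)
        assert with_null == pytest.approx(without, abs=1e-10)

    @pytest.mark.parametrize("gamma", list(product([0, 1], repeat=3)))
    def test_matches_quadrature_oracle(self, gamma):
        z, y = make_problem()
        prior = build_prior(z, y, 2, 0.6, prior_obs_weight=1.0, prior_df=3.0)
        ours = log_marginal(list(gamma), y, z, prior)
        oracle = quadrature_log_marginal(np.array(gamma), z, y, prior)
        # Bayes factors between any two models agree when all log marginals do
        assert ours == pytest.approx(oracle, abs=1e-6)


class TestGibbsSweep:
    def test_zero_spike_probability_never_switches_on(self, rng):
        z, y = make_problem(beta=(3.0, 3.0, 3.0), noise=0.5)
        prior = build_prior(z, y, 2, 0.6)
        prior = type(prior)(
            inclusion_prob=np.array([0.5, 0.0, 0.5]),
            slab_mean=prior.slab_mean,
            slab_information=prior.slab_information,
            variance_prior_df=prior.variance_prior_df,
            variance_prior_sum_of_squares=prior.variance_prior_sum_of_squares,
        )
        current = RegressionDraw(np.zeros(3, dtype=int), np.zeros(3), 1.0)
        for _ in range(50):
            gamma = gibbs_gamma_sweep(current, y, z, prior, rng)
            assert gamma[1] == 0
            current = RegressionDraw(gamma, np.zeros(3), 1.0)

    def test_long_run_frequencies_match_enumeration(self, rng):
        rng_data = np.random.default_rng(5)
        n, k = 20, 3
        x = rng_data.normal(size=(n, k))
        z, _, _ = standardize_design(x)
        y = z @ np.array([1.0, 0.0, -0.6]) + rng_data.normal(0, 1.0, n)
        prior = build_prior(z, y, 1.5, 0.6, prior_obs_weight=1.0)
        exact = enumeration_inclusion_probabilities(z, y, prior)

        ws = SSVSWorkspace(z, prior)
        ws.set_response(y)
        n_sweeps = 40_000
        gamma = np.zeros(k, dtype=np.int8)
        trace = np.empty((n_sweeps, k))
        for i in range(n_sweeps):
            gamma = ws.sweep(gamma, rng)
            trace[i] = gamma
        freq = trace.mean(axis=0)
        # batch-means Monte-Carlo SE to respect chain autocorrelation
        batches = trace.reshape(50, -1, k).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / np.sqrt(50)
        assert np.all(np.abs(freq - exact) < 3 * np.maximum(se, 1e-4))

    def test_dominant_signal_always_included(self, rng):
        rng_data = np.random.default_rng(8)
        n = 25
        x = rng_data.normal(size=(n, 3))
        q, _ = np.linalg.qr(x)
        z, _, _ = standardize_design(q)
        y = 20.0 * z[:, 0] + rng_data.normal(0, 1.0, n)  # effect 20x noise SD
        prior = build_prior(z, y, 1.5, 0.7, prior_obs_weight=1.0)
        ws = SSVSWorkspace(z, prior)
        ws.set_response(y)
        gamma = np.zeros(3, dtype=np.int8)
        hits = 0
        for _ in range(2000):
            gamma = ws.sweep(gamma, rng)
            hits += int(gamma[0])
        assert hits / 2000 > 0.99

    def test_inclusion_monotone_in_effect_size(self):
        rng_data = np.random.default_rng(3)
        n = 25
        x = rng_data.normal(size=(n, 3))
        z, _, _ = standardize_design(x)
        noise = rng_data.normal(0, 1.0, n)
        pips = []
        for effect in (0.0, 0.5, 1.5, 4.0):
            y = effect * z[:, 0] + noise
            prior = build_prior(z, y, 1.5, 0.6, prior_obs_weight=1.0)
            pips.append(enumeration_inclusion_probabilities(z, y, prior)[0])
        assert np.all(np.diff(pips) > 0)


class TestDrawBetaSigma:
    def test_null_gamma_zero_beta_and_invgamma_sigma(self, rng):
        z, y = make_problem(n=10)
        prior = build_prior(z, y, 1.5, 0.6, prior_obs_weight=1.0, prior_df=4.0)
        draws = [draw_beta_sigma([0, 0, 0], y, z, prior, rng) for _ in range(10_000)]
        assert all(np.all(d.coefficients == 0.0) for d in draws)
        sigmas = np.array([d.obs_variance for d in draws])
        a = (len(y) + prior.variance_prior_df) / 2
        scale = (prior.variance_prior_sum_of_squares + y @ y) / 2
        ks = sps.kstest(sigmas, sps.invgamma(a=a, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_ridge_limit_recovers_noiseless_coefficient(self, rng):
        rng_data = np.random.default_rng(4)
        x = rng_data.normal(size=(15, 3))
        z, _, _ = standardize_design(x)
        y = 2.0 * z[:, 0]  # exactly noiseless
        prior = build_prior(z, y, 1.5, 0.6, prior_obs_weight=1e-8)
        gamma = np.array([1, 0, 0])
        # analytic posterior mean oracle
        omega = prior.slab_information[:1, :1]
        analytic = np.linalg.solve(
            omega + z[:, :1].T @ z[:, :1], z[:, :1].T @ y
        ).item()
        assert analytic == pytest.approx(2.0, abs=1e-3)
        betas = np.array(
            [draw_beta_sigma(gamma, y, z, prior, rng).coefficients[0] for _ in range(4000)]
        )
        se = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - analytic) < 3 * max(se, 1e-6)

    def test_posterior_mean_matches_conjugate_formula(self, rng):
        z, y = make_problem(seed=9, n=12, beta=(2.0, -1.0, 0.0), noise=0.8)
        prior = build_prior(z, y, 2, 0.6, prior_obs_weight=1.0)
        gamma = np.array([1, 1, 0])
        idx = [0, 1]
        omega = prior.slab_information[np.ix_(idx, idx)]
        analytic = np.linalg.solve(omega + z[:, idx].T @ z[:, idx], z[:, idx].T @ y)
        betas = np.stack(
            [draw_beta_sigma(gamma, y, z, prior, rng).coefficients[idx] for _ in range(6000)]
        )
        se = betas.std(axis=0, ddof=1) / np.sqrt(len(betas))
        assert np.all(np.abs(betas.mean(axis=0) - analytic) < 3 * se)

    def test_zero_pattern_is_bitwise(self, rng):
        z, y = make_problem(n=15)
        prior = build_prior(z, y, 2, 0.6)
        for _ in range(200):
            gamma = rng.integers(0, 2, size=3)
            d = draw_beta_sigma(gamma, y, z, prior, rng)
            assert np.all(d.coefficients[gamma == 0] == 0.0)
            assert np.all(d.coefficients[gamma == 1] != 0.0)


def test_standardize_rejects_constant_column():
    x = np.ones((10, 2))
    x[:, 0] = np.arange(10)
    with pytest.raises(DegenerateDesignError, match="column 1"):
        standardize_design(x)


def test_regression_draw_validates_zero_pattern():
    with pytest.raises(ValueError):
        RegressionDraw(np.array([0, 1]), np.array([1.0, 2.0]), 1.0)
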