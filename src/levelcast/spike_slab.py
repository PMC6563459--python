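"""Static spike-and-slab regression with conjugate normal--inverse-gamma slab.

The prior on each inclusion indicator ``gamma_k`` is an independent Bernoulli
("spike"); conditional on inclusion, coefficients get a Gaussian slab
``beta_gamma | sigma^2 ~ N(b_gamma, sigma^2 * Omega_gamma^{-1})`` and the
observation variance a conjugate inverse gamma,
``1/sigma^2 ~ Gamma(df/2, ss/2)``.  With beta and sigma^2 integrated out the
marginal likelihood of any inclusion pattern is available in closed form,
which drives single-site Gibbs sweeps over the indicators (stochastic search
variable selection).

:class:`SSVSWorkspace` caches the per-pattern Cholesky factors (the design and
slab are fixed across Gibbs iterations; only the response changes), which is
what makes long MCMC runs affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SpikeSlabPrior",
    "RegressionDraw",
    "SSVSWorkspace",
    "standardize_design",
    "build_prior",
    "log_marginal",
    "gibbs_gamma_sweep",
    "draw_beta_sigma",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class DegenerateDesignError(ValueError):
    """Raised when a covariate column has zero variance."""


class NumericalDegeneracyError(ValueError):
    """Raised when a conditional information matrix is numerically singular."""


@dataclass(frozen=True)
class SpikeSlabPrior:
    """Hyperparameters of the spike-and-slab prior.

    Attributes
    ----------
    inclusion_prob
        Per-covariate Bernoulli inclusion probabilities (the spike), in [0,1].
    slab_mean
        Prior coefficient means (default 0).
    slab_information
        Symmetric PSD prior information scale Omega; the conditional prior on
        included coefficients is N(slab_mean_g, sigma^2 * Omega_gg^{-1}).
    variance_prior_df
        Prior degrees of freedom of the inverse gamma on sigma^2.
    variance_prior_sum_of_squares
        Prior sum of squares of the inverse gamma on sigma^2.
    """

    inclusion_prob: np.ndarray
    slab_mean: np.ndarray
    slab_information: np.ndarray
    variance_prior_df: float
    variance_prior_sum_of_squares: float

    def __post_init__(self) -> None:
        pi = np.asarray(self.inclusion_prob, dtype=float)
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        omega = np.asarray(self.slab_information, dtype=float)
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1] or not np.allclose(
            omega, omega.T
        ):
            raise ValueError("slab_information must be a symmetric matrix")
        if self.variance_prior_df <= 0:
            raise ValueError("variance_prior_df must be positive")
        if self.variance_prior_sum_of_squares <= 0:
            raise ValueError("variance_prior_sum_of_squares must be positive")

    @property
    def n_covariates(self) -> int:
        return len(np.asarray(self.inclusion_prob))


@dataclass(frozen=True)
class RegressionDraw:
    """One Gibbs draw of (gamma, beta, sigma^2); beta is 0 where gamma is 0."""

    inclusion: np.ndarray
    coefficients: np.ndarray
    obs_variance: float

    def __post_init__(self) -> None:
        gamma = np.asarray(self.inclusion)
        beta = np.asarray(self.coefficients)
        if np.any(beta[gamma == 0] != 0.0):
            raise ValueError("coefficients must be exactly zero where gamma = 0")


def standardize_design(covariates, column_names=None):
    """Mean-center and scale columns to unit (n-1 denominator) variance.

    Returns ``(Z, means, scales)``.  Raises :class:`DegenerateDesignError`
    naming the offending column if any column is constant.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim != 2:
        raise ValueError("covariates must be a 2-D array")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(scales <= 0)
    if bad.size:
        name = column_names[bad[0]] if column_names is not None else f"column {bad[0]}"
        raise DegenerateDesignError(f"zero-variance covariate: {name}")
    return (x - means) / scales, means, scales


def build_prior(
    covariates,
    response,
    expected_model_size: float,
    expected_rsq: float,
    prior_obs_weight: float | None = None,
    prior_df: float | None = None,
    diagonal_shrinkage: float = 0.5,
    column_names=None,
) -> SpikeSlabPrior:
    """Construct a spike-and-slab prior from expected model size and R^2.

    Parameters
    ----------
    covariates
        Standardized design matrix (n x K).
    response
        The modelled annual counts (length n); only its sample variance
        enters the prior.
    expected_model_size
        Expected number of non-null coefficients; sets each inclusion
        probability to ``expected_model_size / K``.
    expected_rsq
        Expected explained variance in (0, 1); sets the prior sum of squares
        to ``prior_df * (1 - expected_rsq) * var(response)``.
    prior_obs_weight
        Effective prior sample size; defaults to ``n``.
    prior_df
        Prior degrees of freedom; defaults to ``n - 1``.
    diagonal_shrinkage
        Weight ``w`` averaging the full cross-product with its diagonal in
        the slab information ``(prior_obs_weight / n) * (w X'X + (1-w) diag X'X)``.
    """
    x = np.asarray(covariates, dtype=float)
    y = np.asarray(response, dtype=float)
    n, k = x.shape
    if expected_model_size <= 0 or expected_model_size > k:
        raise ValueError(
            f"expected_model_size must be in (0, {k}], got {expected_model_size}"
        )
    if not 0.0 < expected_rsq < 1.0:
        raise ValueError(f"expected_rsq must be in (0, 1), got {expected_rsq}")
    scales = x.std(axis=0, ddof=1)
    if np.any(scales <= 0):
        bad = int(np.flatnonzero(scales <= 0)[0])
        name = column_names[bad] if column_names is not None else f"column {bad}"
        raise DegenerateDesignError(f"zero-variance covariate: {name}")
    if prior_obs_weight is None:
        prior_obs_weight = float(n)
    if prior_df is None:
        prior_df = float(n - 1)

    s2 = float(np.var(y, ddof=1))
    xtx = x.T @ x
    w = float(diagonal_shrinkage)
    omega = (prior_obs_weight / n) * (w * xtx + (1.0 - w) * np.diag(np.diag(xtx)))
    return SpikeSlabPrior(
        inclusion_prob=np.full(k, expected_model_size / k),
        slab_mean=np.zeros(k),
        slab_information=omega,
        variance_prior_df=float(prior_df),
        variance_prior_sum_of_squares=float(prior_df * (1.0 - expected_rsq) * s2),
    )


class SSVSWorkspace:
    """Reusable sufficient statistics and per-pattern factor cache.

    The design matrix and prior are fixed over a Gibbs run while the response
    (the level-adjusted series) changes every iteration; call
    :meth:`set_response` each time, then use :meth:`log_marginal`,
    :meth:`sweep` and :meth:`draw` freely.
    """

    def __init__(self, covariates, prior: SpikeSlabPrior):
        self.x = np.asarray(covariates, dtype=float)
        self.prior = prior
        self.n = self.x.shape[0]
        self.k = self.x.shape[1]
        if self.k != prior.n_covariates:
            raise ValueError("design and prior dimensions disagree")
        self.xtx = self.x.T @ self.x
        self.omega = np.asarray(prior.slab_information, dtype=float)
        self.b0 = np.asarray(prior.slab_mean, dtype=float)
        self.omega_b0 = self.omega @ self.b0
        self.b0_omega_b0 = float(self.b0 @ self.omega_b0)
        self.xty: np.ndarray | None = None
        self.yty: float | None = None
        # gamma bytes -> (idx, L lower-chol of Vinv, 0.5*(logdet Omega_gg - logdet Vinv))
        self._factors: dict[bytes, tuple] = {}

    def set_response(self, response) -> None:
        y = np.asarray(response, dtype=float)
        if len(y) != self.n:
            raise ValueError("response length does not match design")
        self.xty = self.x.T @ y
        self.yty = float(y @ y)

    def _factor(self, gamma: np.ndarray):
        key = gamma.astype(np.int8).tobytes()
        hit = self._factors.get(key)
        if hit is not None:
            return hit
        idx = np.flatnonzero(gamma != 0)
        if idx.size == 0:
            entry = (idx, None, 0.0)
        else:
            sub = np.ix_(idx, idx)
            omega_g = self.omega[sub]
            vinv = omega_g + self.xtx[sub]
            try:
                low = np.linalg.cholesky(vinv)
            except np.linalg.LinAlgError as exc:
                raise NumericalDegeneracyError(
                    f"singular conditional information matrix for gamma={list(idx)}"
                ) from exc
            sign, logdet_omega = np.linalg.slogdet(omega_g)
            if sign <= 0:
                raise NumericalDegeneracyError(
                    "slab information block not positive definite"
                )
            logdet_vinv = 2.0 * float(np.sum(np.log(np.diag(low))))
            entry = (idx, low, 0.5 * (logdet_omega - logdet_vinv))
        self._factors[key] = entry
        return entry

    def _posterior(self, gamma: np.ndarray):
        """Return (idx, L, mean, ss_post, n_post, logdet_half) for gamma."""
        if self.xty is None:
            raise ValueError("set_response must be called first")
        idx, low, logdet_half = self._factor(gamma)
        df = self.prior.variance_prior_df
        ss = self.prior.variance_prior_sum_of_squares
        n_post = self.n + df
        if idx.size == 0:
            return idx, None, None, ss + self.yty, n_post, logdet_half
        rhs = self.omega_b0[idx] + self.xty[idx]
        # solve Vinv mean = rhs via the cached Cholesky factor
        tmp = np.linalg.solve(low, rhs) if idx.size > 1 else rhs / low[0, 0]
        mean = (
            np.linalg.solve(low.T, tmp) if idx.size > 1 else tmp / low[0, 0]
        )
        b0g = self.b0[idx]
        quad = float(rhs @ mean)
        ss_post = ss + self.yty + float(b0g @ (self.omega[np.ix_(idx, idx)] @ b0g)) - quad
        if ss_post <= 0:  # float cancellation guard
            ss_post = 1e-300
        return idx, low, mean, float(ss_post), n_post, logdet_half

    def log_marginal(self, gamma) -> float:
        """Log marginal likelihood ``log p(response | gamma)``."""
        gamma = np.asarray(gamma, dtype=np.int8)
        idx, _, _, ss_post, n_post, logdet_half = self._posterior(gamma)
        df = self.prior.variance_prior_df
        ss = self.prior.variance_prior_sum_of_squares
        return float(
            -0.5 * self.n * _LOG_2PI
            + 0.5 * df * np.log(0.5 * ss)
            - gammaln(0.5 * df)
            + gammaln(0.5 * n_post)
            - 0.5 * n_post * np.log(0.5 * ss_post)
            + logdet_half
        )

    def sweep(self, gamma, rng: np.random.Generator) -> np.ndarray:
        """One full single-site Gibbs sweep over the inclusion indicators.

        Coordinates are resampled in fixed (column) order from their full
        conditional Bernoulli computed through marginal-likelihood ratios;
        the fixed order makes runs reproducible under a fixed seed.
        """
        gamma = np.asarray(gamma, dtype=np.int8).copy()
        pi = np.asarray(self.prior.inclusion_prob, dtype=float)
        log_m = self.log_marginal(gamma)
        uniforms = rng.random(self.k)
        for k in range(self.k):
            if pi[k] == 0.0:
                if gamma[k] != 0:
                    gamma[k] = 0
                    log_m = self.log_marginal(gamma)
                continue
            if pi[k] == 1.0:
                if gamma[k] != 1:
                    gamma[k] = 1
                    log_m = self.log_marginal(gamma)
                continue
            flipped = gamma.copy()
            flipped[k] = 1 - gamma[k]
            log_m_flip = self.log_marginal(flipped)
            if gamma[k] == 1:
                log_m_on, log_m_off = log_m, log_m_flip
            else:
                log_m_on, log_m_off = log_m_flip, log_m
            log_odds = np.log(pi[k]) - np.log1p(-pi[k]) + log_m_on - log_m_off
            new_val = 1 if uniforms[k] < 1.0 / (1.0 + np.exp(-log_odds)) else 0
            if new_val != gamma[k]:
                gamma = flipped
                log_m = log_m_flip
        return gamma

    def draw(self, gamma, rng: np.random.Generator) -> RegressionDraw:
        """Draw (sigma^2, beta) from their full conditionals given gamma.

        sigma^2 comes from its collapsed inverse-gamma full conditional, then
        the included coefficients from N(posterior mean, sigma^2 V).  Excluded
        coefficients are exactly zero.
        """
        gamma = np.asarray(gamma, dtype=np.int8)
        idx, low, mean, ss_post, n_post, _ = self._posterior(gamma)
        precision = rng.gamma(shape=0.5 * n_post, scale=2.0 / ss_post)
        sigma2 = 1.0 / precision
        beta = np.zeros(self.k)
        if idx.size:
            z = rng.standard_normal(idx.size)
            # N(0, V) deviate: solve L' dev = z with Vinv = L L'
            dev = np.linalg.solve(low.T, z) if idx.size > 1 else z / low[0, 0]
            beta[idx] = mean + np.sqrt(sigma2) * dev
        return RegressionDraw(
            inclusion=gamma.astype(int), coefficients=beta, obs_variance=float(sigma2)
        )


# ---------------------------------------------------------------------------
# functional wrappers (one-shot use)
# ---------------------------------------------------------------------------

def _workspace_for(response, covariates, prior: SpikeSlabPrior) -> SSVSWorkspace:
    ws = SSVSWorkspace(covariates, prior)
    ws.set_response(response)
    return ws


def log_marginal(gamma, response, covariates, prior: SpikeSlabPrior) -> float:
    """Log marginal likelihood ``log p(response | gamma)``.

    beta and sigma^2 are integrated out analytically under the conjugate
    normal--inverse-gamma pair; finite for every gamma with a nonsingular
    conditional information matrix.
    """
    return _workspace_for(response, covariates, prior).log_marginal(gamma)


def gibbs_gamma_sweep(
    current: RegressionDraw,
    response,
    covariates,
    prior: SpikeSlabPrior,
    rng: np.random.Generator,
) -> np.ndarray:
    """One single-site Gibbs sweep over inclusion indicators (fixed order)."""
    gamma = np.asarray(current.inclusion, dtype=int)
    if len(gamma) != prior.n_covariates:
        raise ValueError("inclusion vector length does not match prior")
    return _workspace_for(response, covariates, prior).sweep(gamma, rng).astype(int)


def draw_beta_sigma(
    gamma,
    response,
    covariates,
    prior: SpikeSlabPrior,
    rng: np.random.Generator,
) -> RegressionDraw:
    """Draw (sigma^2, beta) from their full conditionals given gamma."""
    return _workspace_for(response, covariates, prior).draw(gamma, rng)
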