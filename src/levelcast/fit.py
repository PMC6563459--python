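"""Per-area Gibbs sampler for the local-level model with spike-and-slab regressors.

One iteration cycles three blocks:

1. FFBS draw of the level path given current coefficients and variances,
   applied to the regression-adjusted series ``y - X beta``;
2. level-innovation variance draw from its inverse-gamma full conditional
   under ``1/sigma_eta^2 ~ Gamma(shape, rate_factor * s_y^2)``, with the
   innovation SD truncated at an upper limit expressed as a fraction of the
   series SD;
3. spike-and-slab indicator sweep plus a joint (sigma_eps^2, beta) draw on
   the level-adjusted series ``y - mu``.

Models are fitted independently per area (no pooling, no spatial terms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import spike_slab, state_space
from .spike_slab import RegressionDraw, build_prior, standardize_design
from .state_space import LocalLevelParams, ffbs_draw, kalman_filter

__all__ = ["FitConfig", "PosteriorDraws", "series_variance", "fit_model"]

#: Shortest training series the sampler accepts.
MIN_TRAINING_LENGTH = 8


class InsufficientDataError(ValueError):
    """Raised when the training series is shorter than the supported minimum."""


@dataclass(frozen=True)
class LevelSdFractions:
    """Level-SD prior settings expressed as fractions of the series SD."""

    prior_guess: float = 0.01
    initial: float = 0.05
    upper_limit: float = 1.50


@dataclass(frozen=True)
class FitConfig:
    """Sampler configuration.

    Defaults follow the production settings: 20,000 iterations with a 10%
    burn-in, expected model size 5, expected explained variance 70%, and a
    Gamma(0.01, 0.01 * s_y^2) prior on the level-innovation precision.
    """

    n_iterations: int = 20_000
    burn_in_fraction: float = 0.10
    seed: int = 0
    expected_model_size: float = 5.0
    expected_rsq: float = 0.70
    variance_gamma_shape: float = 0.01
    variance_gamma_rate_factor: float = 0.01
    level_sd_fractions: LevelSdFractions = field(default_factory=LevelSdFractions)
    diagonal_shrinkage: float = 0.5
    level_prior: str = "diffuse"  # "diffuse" or "informative"
    #: effective prior sample size of the slab; kept small so the slab stays
    #: weakly informative and the data dominate coefficient estimation
    prior_obs_weight: float = 0.01
    #: prior on the level-innovation precision: "small-sd" centres the
    #: innovation SD a priori at ``level_sd_fractions.prior_guess * s_y``
    #: with ``level_prior_weight`` degrees of freedom; "gamma-sy2" uses
    #: Gamma(variance_gamma_shape, variance_gamma_rate_factor * s_y^2)
    level_variance_prior: str = "small-sd"
    level_prior_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if self.level_prior not in ("diffuse", "informative"):
            raise ValueError("level_prior must be 'diffuse' or 'informative'")
        if self.level_variance_prior not in ("small-sd", "gamma-sy2"):
            raise ValueError("level_variance_prior must be 'small-sd' or 'gamma-sy2'")

    @property
    def n_burn_in(self) -> int:
        """Burn-in length, rounded to the nearest integer."""
        return int(round(self.burn_in_fraction * self.n_iterations))

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_burn_in


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one area.

    ``coefficients`` are on the original covariate scale (counts per unit of
    the raw covariate); the fitted level plays the role of the intercept, so
    predictions combine coefficients with *centered* raw covariates (see
    :mod:`levelcast.predict`).
    """

    level_paths: np.ndarray  # (draws, T)
    obs_variances: np.ndarray  # (draws,)
    level_variances: np.ndarray  # (draws,)
    coefficients: np.ndarray  # (draws, K) original scale
    inclusions: np.ndarray  # (draws, K) binary
    log_likelihoods: np.ndarray  # (draws,)
    covariate_mean: np.ndarray  # (K,) raw-scale training means
    covariate_names: list[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.level_paths.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.coefficients.shape[1]


def series_variance(values) -> float:
    """Sample variance with the (n-1) denominator."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("series_variance requires a 1-D series of length >= 2")
    return float(np.var(y, ddof=1))


def _draw_level_variance(
    level_path: np.ndarray,
    shape0: float,
    rate0: float,
    sd_cap: float,
    rng: np.random.Generator,
    max_tries: int = 100,
) -> float:
    """Inverse-gamma full-conditional draw of the level-innovation variance.

    The innovation SD is truncated at ``sd_cap`` by rejection; if rejection
    fails repeatedly (pathological data) the cap itself is returned.
    """
    diffs = np.diff(level_path)
    shape = shape0 + 0.5 * len(diffs)
    rate = rate0 + 0.5 * float(diffs @ diffs)
    for _ in range(max_tries):
        precision = rng.gamma(shape=shape, scale=1.0 / rate)
        var = 1.0 / precision
        if var <= sd_cap * sd_cap:
            return var
    return sd_cap * sd_cap


def fit_model(response, covariates, config: FitConfig, covariate_names=None) -> PosteriorDraws:
    """Run the three-block Gibbs sampler on one area's training data.

    Parameters
    ----------
    response
        Contiguous training series of annual counts, length >= 8.
    covariates
        Raw-scale design matrix aligned to the training years (n x K).
    config
        Sampler settings; identical inputs and seed give identical draws.

    Returns
    -------
    PosteriorDraws
        The retained draws after burn-in.
    """
    y = np.asarray(response, dtype=float)
    x_raw = np.asarray(covariates, dtype=float)
    if y.ndim != 1:
        raise ValueError("response must be one-dimensional")
    if len(y) < MIN_TRAINING_LENGTH:
        raise InsufficientDataError(
            f"training series has {len(y)} points; at least {MIN_TRAINING_LENGTH} required"
        )
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(x_raw)):
        raise ValueError("non-finite values in training data")
    if x_raw.shape[0] != len(y):
        raise ValueError("covariates and response have mismatched lengths")

    n, k = x_raw.shape
    rng = np.random.default_rng(config.seed)

    z, x_mean, x_scale = standardize_design(x_raw, column_names=covariate_names)
    s_y2 = series_variance(y)
    s_y = math.sqrt(s_y2) if s_y2 > 0 else 1.0

    prior = build_prior(
        z,
        y,
        expected_model_size=min(config.expected_model_size, k),
        expected_rsq=config.expected_rsq,
        prior_obs_weight=config.prior_obs_weight,
        prior_df=float(n - 1),
        diagonal_shrinkage=config.diagonal_shrinkage,
        column_names=covariate_names,
    )
    workspace = spike_slab.SSVSWorkspace(z, prior)

    # Level prior: diffuse-by-large-variance, or anchored at the first value.
    if config.level_prior == "informative":
        init_mean, init_var = float(y[0]), max(s_y2, 1.0)
    else:
        init_mean, init_var = float(y[0]), 1e6 * max(s_y2, 1.0)

    frac = config.level_sd_fractions
    if config.level_variance_prior == "small-sd":
        # innovation SD a priori small: guess = prior_guess * s_y
        eta_shape0 = 0.5 * config.level_prior_weight
        eta_rate0 = 0.5 * config.level_prior_weight * max(
            (frac.prior_guess * s_y) ** 2, 1e-12
        )
    else:  # literal Gamma(shape, rate_factor * s_y^2) on the precision
        eta_shape0 = config.variance_gamma_shape
        eta_rate0 = config.variance_gamma_rate_factor * max(s_y2, 1e-12)
    eta_sd_cap = frac.upper_limit * s_y

    # starting values
    level = y.copy()
    sigma2_eps = max(s_y2, 1e-12)
    sigma2_eta = (frac.initial * s_y) ** 2
    reg = RegressionDraw(
        inclusion=np.zeros(k, dtype=int),
        coefficients=np.zeros(k),
        obs_variance=sigma2_eps,
    )

    n_keep = config.n_retained
    out_levels = np.empty((n_keep, n))
    out_obs_var = np.empty(n_keep)
    out_lvl_var = np.empty(n_keep)
    out_beta = np.empty((n_keep, k))
    out_gamma = np.empty((n_keep, k), dtype=np.int8)
    out_loglik = np.empty(n_keep)

    n_burn = config.n_burn_in
    for it in range(config.n_iterations):
        # block 1: level path given regression and variances
        adjusted = y - z @ reg.coefficients
        params = LocalLevelParams(
            obs_variance=max(reg.obs_variance, 1e-12),
            level_variance=sigma2_eta,
            level_init_mean=init_mean,
            level_init_variance=init_var,
        )
        fstate = kalman_filter(adjusted, params)
        level = ffbs_draw(fstate, params, rng)

        # block 2: level-innovation variance (truncated inverse gamma)
        sigma2_eta = _draw_level_variance(level, eta_shape0, eta_rate0, eta_sd_cap, rng)

        # block 3: spike-and-slab on the level-adjusted series
        workspace.set_response(y - level)
        gamma = workspace.sweep(reg.inclusion, rng)
        reg = workspace.draw(gamma, rng)

        if it >= n_burn:
            j = it - n_burn
            out_levels[j] = level
            out_obs_var[j] = reg.obs_variance
            out_lvl_var[j] = sigma2_eta
            out_beta[j] = reg.coefficients / x_scale  # original scale
            out_gamma[j] = reg.inclusion
            out_loglik[j] = fstate.log_likelihood

    return PosteriorDraws(
        level_paths=out_levels,
        obs_variances=out_obs_var,
        level_variances=out_lvl_var,
        coefficients=out_beta,
        inclusions=out_gamma,
        log_likelihoods=out_loglik,
        covariate_mean=x_mean,
        covariate_names=list(covariate_names) if covariate_names is not None else None,
    )
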