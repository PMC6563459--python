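"""Posterior-predictive now/forecasting with model averaging over draws.

Each retained Gibbs draw carries its own level endpoint, variances and
(possibly different) set of included covariates; simulating every draw
forward and pooling the results performs Bayesian model averaging over the
inclusion patterns implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fit import PosteriorDraws

__all__ = ["ForecastResult", "posterior_predictive", "inclusion_probabilities"]

logger = logging.getLogger(__name__)


@dataclass
class ForecastResult:
    """Posterior-predictive draws and summaries for one area.

    The point estimate is the posterior-predictive median; the mean is also
    provided.  Intervals are equal-tailed 95% (2.5% / 97.5% quantiles).
    Negative predictive draws are retained (the Gaussian observation model
    can produce them); a warning is logged when more than 1% of draws are
    negative.
    """

    horizon_years: np.ndarray
    predictive_draws: np.ndarray  # (draws, horizon)
    point_estimate: np.ndarray
    mean_estimate: np.ndarray
    lower_95: np.ndarray
    upper_95: np.ndarray
    inclusion_probabilities: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.predictive_draws.shape[0]


def inclusion_probabilities(draws: PosteriorDraws) -> np.ndarray:
    """Marginal posterior inclusion probability per covariate (column means)."""
    if draws.n_draws < 1:
        raise ValueError("at least one retained draw is required")
    return draws.inclusions.mean(axis=0)


def summarize_draws(predictive: np.ndarray, horizon_years, pip) -> ForecastResult:
    """Build a :class:`ForecastResult` from a (draws x horizon) matrix."""
    frac_negative = float(np.mean(predictive < 0))
    if frac_negative > 0.01:
        logger.warning(
            "%.1f%% of predictive draws are negative; retained untruncated",
            100 * frac_negative,
        )
    return ForecastResult(
        horizon_years=np.asarray(horizon_years),
        predictive_draws=predictive,
        point_estimate=np.median(predictive, axis=0),
        mean_estimate=predictive.mean(axis=0),
        lower_95=np.quantile(predictive, 0.025, axis=0),
        upper_95=np.quantile(predictive, 0.975, axis=0),
        inclusion_probabilities=np.asarray(pip, dtype=float),
    )


def posterior_predictive(
    draws: PosteriorDraws,
    future_covariates,
    horizon_years,
    rng: np.random.Generator,
) -> ForecastResult:
    """Simulate the posterior predictive over the given horizon.

    For each retained draw the level is propagated forward as a random walk
    with that draw's innovation variance, that draw's regression contribution
    ``beta'(x_future - x_mean_train)`` is added, and Gaussian observation
    noise with that draw's variance is applied.

    Parameters
    ----------
    draws
        Retained posterior draws for one area.
    future_covariates
        Raw-scale design rows, one per forecast year (horizon x K).
    horizon_years
        Year keys of the forecast rows (length horizon).
    rng
        Seeded random source.
    """
    x_future = np.atleast_2d(np.asarray(future_covariates, dtype=float))
    horizon_years = np.asarray(horizon_years)
    horizon = len(horizon_years)
    if x_future.shape[0] != horizon:
        raise ValueError(
            f"future_covariates has {x_future.shape[0]} rows but horizon is {horizon}"
        )
    if x_future.shape[1] != draws.n_covariates:
        raise ValueError("future covariate dimension does not match the fit")

    g = draws.n_draws
    last_levels = draws.level_paths[:, -1]
    # forward random walk per draw, vectorized across draws
    steps = rng.standard_normal((g, horizon)) * np.sqrt(draws.level_variances)[:, None]
    levels = last_levels[:, None] + np.cumsum(steps, axis=1)
    # regression contribution: level absorbs the training-mean offset
    centered = x_future - draws.covariate_mean  # (horizon, K)
    reg = draws.coefficients @ centered.T  # (g, horizon)
    noise = rng.standard_normal((g, horizon)) * np.sqrt(draws.obs_variances)[:, None]
    predictive = levels + reg + noise
    return summarize_draws(predictive, horizon_years, inclusion_probabilities(draws))
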