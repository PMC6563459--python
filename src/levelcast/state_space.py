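"""Local-level state-space model: Kalman filtering, FFBS and level simulation.

The observation model is ``y_t = mu_t + eps_t`` with ``eps_t ~ N(0, obs_variance)``
and the latent level follows a Gaussian random walk
``mu_{t+1} = mu_t + eta_t`` with ``eta_t ~ N(0, level_variance)``.

All recursions are carried in variance (not precision) form.  Every stochastic
operation takes an explicit :class:`numpy.random.Generator`; nothing touches
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocalLevelParams",
    "FilterState",
    "kalman_filter",
    "ffbs_draw",
    "simulate_level_path",
]

# Floor applied to predicted variances to guard against negative values
# produced by floating-point cancellation.
_VARIANCE_FLOOR = 1e-12


class InvalidParameterError(ValueError):
    """Raised when state-space parameters violate their invariants."""


class ContiguityError(ValueError):
    """Raised when a series contains missing / non-finite values."""


@dataclass(frozen=True)
class LocalLevelParams:
    """Parameters of the local-level model.

    Parameters
    ----------
    obs_variance
        Observation-noise variance (count^2 units); must be > 0.
    level_variance
        Random-walk innovation variance (count^2 units); must be >= 0.
    level_init_mean
        Prior mean of the level at t=1.
    level_init_variance
        Prior variance of the level at t=1; must be > 0.
    """

    obs_variance: float
    level_variance: float
    level_init_mean: float = 0.0
    level_init_variance: float = 1e6

    def __post_init__(self) -> None:
        if not np.isfinite(self.obs_variance) or self.obs_variance <= 0:
            raise InvalidParameterError(
                f"obs_variance must be positive, got {self.obs_variance!r}"
            )
        if not np.isfinite(self.level_variance) or self.level_variance < 0:
            raise InvalidParameterError(
                f"level_variance must be nonnegative, got {self.level_variance!r}"
            )
        if not np.isfinite(self.level_init_variance) or self.level_init_variance <= 0:
            raise InvalidParameterError(
                f"level_init_variance must be positive, got {self.level_init_variance!r}"
            )


@dataclass(frozen=True)
class FilterState:
    """Output of the forward Kalman pass over one series."""

    filtered_mean: np.ndarray
    filtered_variance: np.ndarray
    predicted_mean: np.ndarray
    predicted_variance: np.ndarray
    innovation: np.ndarray
    innovation_variance: np.ndarray
    log_likelihood: float
    series: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.filtered_mean)


def _check_series(series) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ContiguityError("series contains missing or non-finite values")
    return y


def kalman_filter(series, params: LocalLevelParams) -> FilterState:
    """Run the exact Gaussian filtering recursion on a contiguous series.

    Parameters
    ----------
    series
        Regression-adjusted annual values, length >= 2, no missing values.
    params
        Valid :class:`LocalLevelParams`.

    Returns
    -------
    FilterState
        Per-step filtered and one-step-predicted moments, innovations, and
        the total Gaussian log-likelihood (sum of innovation log-densities).
    """
    y = _check_series(series)
    if len(y) < 2:
        raise ValueError(f"series length must be >= 2, got {len(y)}")

    n = len(y)
    fm = np.empty(n)
    fv = np.empty(n)
    pm = np.empty(n)
    pv = np.empty(n)
    innov = np.empty(n)
    innov_var = np.empty(n)

    a = params.level_init_mean
    p = params.level_init_variance
    loglik = 0.0
    for t in range(n):
        pm[t] = a
        pv[t] = p
        f = p + params.obs_variance
        v = y[t] - a
        innov[t] = v
        innov_var[t] = f
        loglik += -0.5 * (np.log(2.0 * np.pi * f) + v * v / f)
        gain = p / f
        a = a + gain * v
        p = max(p * (1.0 - gain), _VARIANCE_FLOOR)
        fm[t] = a
        fv[t] = p
        p = p + params.level_variance  # time update for next step

    return FilterState(
        filtered_mean=fm,
        filtered_variance=fv,
        predicted_mean=pm,
        predicted_variance=pv,
        innovation=innov,
        innovation_variance=innov_var,
        log_likelihood=float(loglik),
        series=y,
    )


def ffbs_draw(
    filter_state: FilterState,
    params: LocalLevelParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw level path(s) from the joint smoothing distribution (FFBS).

    Backward-samples ``mu_{1:T} | y_{1:T}`` exactly, starting from the final
    filtered distribution and conditioning each earlier level on the draw one
    step ahead.

    Parameters
    ----------
    filter_state
        Output of :func:`kalman_filter` run with the same ``params``.
    params
        The parameters used in the forward pass.
    rng
        Seeded random source.
    size
        If ``None`` return one path of shape ``(T,)``; otherwise return
        ``(size, T)`` independent paths.

    Returns
    -------
    numpy.ndarray
        Exact draw(s) from the smoothing distribution of the level path.
    """
    fm = filter_state.filtered_mean
    fv = filter_state.filtered_variance
    n = len(fm)
    if n != len(filter_state.predicted_mean):
        raise ValueError("inconsistent filter state lengths")

    m = 1 if size is None else int(size)
    path = np.empty((m, n))
    path[:, -1] = fm[-1] + np.sqrt(fv[-1]) * rng.standard_normal(m)
    q = params.level_variance
    for t in range(n - 2, -1, -1):
        denom = fv[t] + q
        if denom <= 0.0:
            # both variances degenerate: level is pinned at the filtered mean
            path[:, t] = path[:, t + 1]
            continue
        gain = fv[t] / denom
        cond_mean = fm[t] + gain * (path[:, t + 1] - fm[t])
        cond_var = max(fv[t] * (1.0 - gain), 0.0)
        path[:, t] = cond_mean + np.sqrt(cond_var) * rng.standard_normal(m)
    return path[0] if size is None else path


def simulate_level_path(
    last_level: float,
    params: LocalLevelParams,
    horizon: int,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Iterate the random walk ``horizon`` steps beyond ``last_level``.

    With ``level_variance == 0`` the path is constant at ``last_level``.
    Returns shape ``(horizon,)``, or ``(size, horizon)`` when ``size`` given.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    m = 1 if size is None else int(size)
    steps = np.sqrt(params.level_variance) * rng.standard_normal((m, horizon))
    path = last_level + np.cumsum(steps, axis=1)
    return path[0] if size is None else path
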