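"""MCMC and residual diagnostic gates.

Four gates are applied to each fitted model: the Raftery--Lewis dependence
factor (pass if I < 5), the Geweke comparison of early and late chain means
(pass if |z| <= 1.96), the Heidelberger--Welch stationarity test at alpha
0.05, and the Durbin--Watson statistic of the one-step prediction errors
(pass if inside a configurable band, default [1.5, 2.5]).

All four statistics are deterministic functions of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DiagnosticsReport",
    "geweke_z",
    "raftery_lewis_I",
    "heidelberger_welch",
    "durbin_watson",
    "evaluate_chain",
    "diagnose_draws",
]

#: Asymptotic critical values of the one-sample Cramer--von Mises statistic.
_CVM_CRITICAL = {0.10: 0.3473, 0.05: 0.4614, 0.025: 0.5806, 0.01: 0.7435}

DEFAULT_DW_BAND = (1.5, 2.5)


class DegenerateChainError(ValueError):
    """Raised when a chain has (numerically) zero variance."""


class InsufficientLengthError(ValueError):
    """Raised when a chain is too short for the requested diagnostic."""

    def __init__(self, message: str, minimum: int):
        super().__init__(message)
        self.minimum = minimum


@dataclass(frozen=True)
class DiagnosticsReport:
    """Per-chain gate results; ``passed`` is the conjunction of all gates."""

    raftery_lewis_I: float
    geweke_z: float
    heidelberger_welch_pass: bool
    hw_discarded_fraction: float
    durbin_watson: float
    passed: bool


def _spectral_density_zero(x: np.ndarray) -> float:
    """Bartlett-window estimate of the spectral density at frequency zero.

    Uses lag truncation ``L = floor(sqrt(n))`` with weights ``1 - l/(L+1)``;
    autocovariances use the n-denominator convention.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    lmax = int(math.floor(math.sqrt(n)))
    acov = np.correlate(xc, xc, mode="full")[n - 1 : n + lmax] / n
    weights = 1.0 - np.arange(1, lmax + 1) / (lmax + 1.0)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:]))


def geweke_z(chain, first_fraction: float = 0.1, last_fraction: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late window means.

    ``z = (mean_first - mean_last) / sqrt(S_first(0)/n_first + S_last(0)/n_last)``
    where S(0) is the spectral density at zero of each window.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise InsufficientLengthError(f"chain length {n} < 100", 100)
    if np.var(x) == 0:
        raise DegenerateChainError("zero-variance chain")
    n_a = int(first_fraction * n)
    n_b = int(last_fraction * n)
    a, b = x[:n_a], x[n - n_b :]
    var = _spectral_density_zero(a) / n_a + _spectral_density_zero(b) / n_b
    if var <= 0:
        raise DegenerateChainError("non-positive spectral variance estimate")
    return float((a.mean() - b.mean()) / math.sqrt(var))


def _thinned_markov_order_ok(z: np.ndarray) -> bool:
    """BIC check that the dichotomized chain is adequately first-order Markov."""
    n = len(z)
    counts = np.zeros((2, 2, 2))
    np.add.at(counts, (z[:-2], z[1:-1], z[2:]), 1)
    # G2 for conditional independence of z_{t-2} and z_t given z_{t-1}
    g2 = 0.0
    for j in range(2):
        slice_ = counts[:, j, :]
        tot = slice_.sum()
        if tot == 0:
            continue
        expected = np.outer(slice_.sum(axis=1), slice_.sum(axis=0)) / tot
        mask = slice_ > 0
        g2 += 2.0 * float(np.sum(slice_[mask] * np.log(slice_[mask] / expected[mask])))
    bic = g2 - math.log(n - 2) * 2.0
    return bic < 0


def raftery_lewis_I(
    chain,
    quantile: float = 0.025,
    precision: float = 0.005,
    coverage: float = 0.95,
) -> float:
    """Raftery--Lewis dependence factor I for estimating a tail quantile.

    The chain is dichotomized at the empirical ``quantile``; a thinning factor
    is chosen by a BIC first-order-Markov check, the two-state transition
    probabilities are estimated, and I is the ratio of required iterations
    (burn-in plus estimation) to the minimum iid count.
    """
    x = np.asarray(chain, dtype=float)
    phi = sps.norm.ppf(0.5 * (1.0 + coverage))
    n_min = int(math.ceil(quantile * (1.0 - quantile) * (phi / precision) ** 2))
    if len(x) < n_min:
        raise InsufficientLengthError(
            f"chain length {len(x)} below Raftery-Lewis minimum {n_min}", n_min
        )
    cutoff = np.quantile(x, quantile)
    z_full = (x <= cutoff).astype(int)

    kthin = 1
    while True:
        z = z_full[::kthin]
        if len(z) < 3 or _thinned_markov_order_ok(z):
            break
        kthin += 1

    transitions = np.zeros((2, 2))
    np.add.at(transitions, (z[:-1], z[1:]), 1)
    row = transitions.sum(axis=1)
    # degenerate dichotomization: fall back to independence
    alpha = transitions[0, 1] / row[0] if row[0] > 0 else quantile
    beta = transitions[1, 0] / row[1] if row[1] > 0 else 1.0 - quantile
    alpha = min(max(alpha, 1e-12), 1 - 1e-12)
    beta = min(max(beta, 1e-12), 1 - 1e-12)

    eps = 0.001
    lam = 1.0 - alpha - beta
    if abs(lam) > 0:
        m = math.log(eps * (alpha + beta) / max(alpha, beta)) / math.log(abs(lam))
        n_burn = int(math.ceil(m)) * kthin
    else:
        n_burn = kthin
    n_keep = (
        int(
            math.ceil(
                (2.0 - alpha - beta)
                * alpha
                * beta
                * phi**2
                / ((alpha + beta) ** 3 * precision**2)
            )
        )
        * kthin
    )
    return float((n_burn + n_keep) / n_min)


def heidelberger_welch(chain, alpha: float = 0.05) -> tuple[bool, float]:
    """Heidelberger--Welch stationarity test.

    Iteratively discards initial 10% increments (up to 50%) and applies the
    Cramer--von Mises test to the Brownian-bridge transform of the cumulative
    sums, using a spectral variance estimated from the final half of the full
    chain.  Returns ``(passed, fraction_discarded)``.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise InsufficientLengthError(f"chain length {n} < 100", 100)
    if np.var(x) == 0:
        raise DegenerateChainError("zero-variance chain")
    critical = _CVM_CRITICAL.get(round(alpha, 4))
    if critical is None:
        raise ValueError(f"unsupported alpha {alpha}; use one of {sorted(_CVM_CRITICAL)}")
    s0 = _spectral_density_zero(x[n // 2 :])
    if s0 <= 0:
        raise DegenerateChainError("non-positive spectral variance estimate")
    for frac in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
        sub = x[int(frac * n) :]
        m = len(sub)
        csum = np.cumsum(sub)
        k = np.arange(1, m + 1)
        bridge = (csum - k * sub.mean()) / math.sqrt(m * s0)
        cvm = float(np.sum(bridge**2) / m)
        if cvm < critical:
            return True, frac
    return False, 0.5


def durbin_watson(residuals) -> float:
    """Durbin--Watson statistic of one-step prediction errors, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if len(e) < 3:
        raise ValueError("at least 3 residuals required")
    denom = float(e @ e)
    if denom == 0:
        raise DegenerateChainError("all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def evaluate_chain(
    chain,
    residuals,
    dw_band: tuple[float, float] = DEFAULT_DW_BAND,
    geweke_threshold: float = 1.96,
    rl_threshold: float = 5.0,
    hw_alpha: float = 0.05,
) -> DiagnosticsReport:
    """Apply all four gates to one chain plus its model's nowcast residuals."""
    z = geweke_z(chain)
    rl = raftery_lewis_I(chain)
    hw_pass, hw_frac = heidelberger_welch(chain, alpha=hw_alpha)
    dw = durbin_watson(residuals)
    passed = (
        rl < rl_threshold
        and abs(z) <= geweke_threshold
        and hw_pass
        and dw_band[0] <= dw <= dw_band[1]
    )
    return DiagnosticsReport(
        raftery_lewis_I=rl,
        geweke_z=z,
        heidelberger_welch_pass=hw_pass,
        hw_discarded_fraction=hw_frac,
        durbin_watson=dw,
        passed=passed,
    )


def nowcast_residuals(draws, response, covariates) -> np.ndarray:
    """One-step prediction errors at posterior-mean parameters.

    The series is regression-adjusted with the posterior-mean coefficients and
    filtered with the posterior-mean variances; the filter innovations are the
    nowcast residuals whose serial correlation the Durbin--Watson gate checks.
    """
    from .state_space import LocalLevelParams, kalman_filter

    y = np.asarray(response, dtype=float)
    x = np.asarray(covariates, dtype=float)
    beta = draws.coefficients.mean(axis=0)
    adjusted = y - (x - draws.covariate_mean) @ beta
    params = LocalLevelParams(
        obs_variance=float(np.mean(draws.obs_variances)),
        level_variance=float(np.mean(draws.level_variances)),
        level_init_mean=float(adjusted[0]),
        level_init_variance=1e6 * max(float(np.var(y, ddof=1)), 1.0),
    )
    state = kalman_filter(adjusted, params)
    # drop the first innovation: dominated by the diffuse prior
    return state.innovation[1:]


def diagnose_draws(draws, response, covariates, min_inclusion_draws: int = 100, **gate_kwargs):
    """Gate every monitored chain of one fit; returns a list of row dicts.

    Chains monitored: the log-likelihood trace, both variance chains, and each
    coefficient chain restricted to draws where it is included.  Chains too
    short for a gate (e.g. rarely-included coefficients) report that statistic
    as NaN and the gate is skipped for them.
    """
    residuals = nowcast_residuals(draws, response, covariates)
    chains = {
        "log_likelihood": draws.log_likelihoods,
        "obs_variance": draws.obs_variances,
        "level_variance": draws.level_variances,
    }
    names = draws.covariate_names or [f"x{k}" for k in range(draws.n_covariates)]
    for k, name in enumerate(names):
        included = draws.inclusions[:, k] == 1
        if included.sum() >= min_inclusion_draws:
            chains[f"beta_{name}"] = draws.coefficients[included, k]

    rows = []
    for name, chain in chains.items():
        row = {"chain": name}
        try:
            report = evaluate_chain(chain, residuals, **gate_kwargs)
            row.update(
                raftery_lewis_I=report.raftery_lewis_I,
                geweke_z=report.geweke_z,
                heidelberger_welch_pass=report.heidelberger_welch_pass,
                hw_discarded_fraction=report.hw_discarded_fraction,
                durbin_watson=report.durbin_watson,
                passed=report.passed,
            )
        except (InsufficientLengthError, DegenerateChainError) as exc:
            row.update(
                raftery_lewis_I=float("nan"),
                geweke_z=float("nan"),
                heidelberger_welch_pass=False,
                hw_discarded_fraction=float("nan"),
                durbin_watson=float("nan"),
                passed=False,
                note=str(exc),
            )
        rows.append(row)
    return rows
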