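"""Synthetic panel generator with known ground truth.

Emulates the structure of the real inputs: per-area annual event counts
driven by a random-walk level plus a sparse linear signal from age-stratum
populations, and smooth stratified population trajectories with deterministic
projections beyond the observed window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STRATA",
    "SyntheticConfig",
    "SyntheticPanel",
    "generate_populations",
    "generate_admissions",
    "generate_panel",
]

logger = logging.getLogger(__name__)

#: Age-stratum column names (eight strata plus a derived total).
STRATA = (
    "pop_0_15",
    "pop_16_24",
    "pop_25_34",
    "pop_35_44",
    "pop_45_54",
    "pop_55_64",
    "pop_65_74",
    "pop_75plus",
)
COVARIATE_COLUMNS = ("pop_total",) + STRATA


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; same config + seed gives byte-identical panels."""

    n_areas: int = 20
    n_years_observed: int = 13
    n_years_projected: int = 5
    first_year: int = 2003
    seed: int = 0
    #: true coefficients per covariate column (counts per thousand persons);
    #: sparse by default — at most the expected model size are nonzero.
    true_coefficients: tuple = (0.0, 0.0, 3.0, 0.0, 0.0, -2.0, 0.0, 0.0, 0.0)
    level_innovation_sd: float = 5.0
    obs_noise_sd: float = 15.0
    base_rate_per_1000: float = 6.0
    population_base_range: tuple = (4_000.0, 40_000.0)
    population_trend_range: tuple = (-800.0, 800.0)
    population_wiggle_sd: float = 30.0
    #: when set, rescale each nonzero coefficient per area so that its own
    #: signal sd over the observed years, sd(beta_k * x_k) / obs_noise_sd,
    #: equals this target; the per-area truth records the rescaled values
    target_snr: float | None = None

    def __post_init__(self) -> None:
        if self.n_areas < 1 or self.n_years_observed < 2 or self.n_years_projected < 0:
            raise ValueError("invalid synthetic panel dimensions")
        if len(self.true_coefficients) != len(COVARIATE_COLUMNS):
            raise ValueError(
                f"true_coefficients must have {len(COVARIATE_COLUMNS)} entries "
                f"(columns {COVARIATE_COLUMNS})"
            )
        if self.obs_noise_sd <= 0 or self.level_innovation_sd < 0:
            raise ValueError("noise SDs out of range")


@dataclass
class SyntheticPanel:
    """Generated panel plus the ground truth that produced it."""

    frame: pd.DataFrame  # long format, one row per (area, year)
    truth: dict  # area_id -> {"level": path, "coefficients": ..., ...}
    config: SyntheticConfig


def _paper_scale(config: SyntheticConfig | None = None) -> SyntheticConfig:
    """Preset mirroring the full study dimensions (324 areas, 13 + 5 years)."""
    return SyntheticConfig(n_areas=324, n_years_observed=13, n_years_projected=5)


def generate_populations(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-area stratified population trajectories (observed + projected).

    Each stratum follows an area-specific linear trend with small Gaussian
    wiggle over the observed years; projected years extrapolate the trend
    deterministically (no wiggle).  ``pop_total`` is the exact stratum sum.
    """
    n_obs = config.n_years_observed
    n_all = n_obs + config.n_years_projected
    years = config.first_year + np.arange(n_all)
    rows = []
    for a in range(config.n_areas):
        area_id = f"A{a:03d}"
        base = rng.uniform(*config.population_base_range, size=len(STRATA))
        trend = rng.uniform(*config.population_trend_range, size=len(STRATA))
        t = np.arange(n_all)
        pops = base[None, :] + trend[None, :] * t[:, None]
        wiggle = rng.normal(0.0, config.population_wiggle_sd, size=(n_obs, len(STRATA)))
        pops[:n_obs] += wiggle
        pops = np.maximum(pops, 100.0)  # keep strata positive
        for i, year in enumerate(years):
            row = {"area_id": area_id, "year": int(year), "is_projected": i >= n_obs}
            row.update({s: float(pops[i, j]) for j, s in enumerate(STRATA)})
            row["pop_total"] = float(pops[i].sum())
            rows.append(row)
    return pd.DataFrame(rows)


def generate_admissions(
    populations: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Simulate observed counts on top of the population trajectories.

    ``y_t = mu_t + sum_k beta_k * (pop_k_t / 1000) + eps_t`` with ``mu`` a
    random walk started near ``base_rate_per_1000`` admissions per 1,000
    total population.  Counts are generated for observed years only; negative
    values are floored at zero with a logged count.  Returns the panel frame
    (admissions NaN in projected years) and the truth record.
    """
    beta = np.asarray(config.true_coefficients, dtype=float)
    frame = populations.copy()
    frame["admissions"] = np.nan
    truth: dict = {}
    n_floored = 0
    for area_id, sub in frame.groupby("area_id", sort=True):
        obs = sub[~sub["is_projected"]].sort_values("year")
        n_obs = len(obs)
        x = obs[list(COVARIATE_COLUMNS)].to_numpy() / 1000.0
        area_beta = beta.copy()
        if config.target_snr is not None:
            for k in np.flatnonzero(beta):
                col_sd = float(np.std(x[:, k], ddof=1))
                if col_sd > 0:
                    area_beta[k] = (
                        np.sign(beta[k])
                        * config.target_snr
                        * config.obs_noise_sd
                        / col_sd
                    )
        signal = x @ area_beta
        mu0 = config.base_rate_per_1000 * float(obs["pop_total"].iloc[0]) / 1000.0
        # center the signal so the level sets the overall scale
        mu0 -= float(signal.mean())
        steps = rng.normal(0.0, config.level_innovation_sd, size=n_obs)
        steps[0] = 0.0
        level = mu0 + np.cumsum(steps)
        noise = rng.normal(0.0, config.obs_noise_sd, size=n_obs)
        y = level + signal + noise
        floored = y < 0
        n_floored += int(floored.sum())
        y = np.maximum(y, 0.0)
        frame.loc[obs.index, "admissions"] = y
        truth[area_id] = {
            "level": level,
            "coefficients": area_beta.copy(),
            "level_innovation_sd": config.level_innovation_sd,
            "obs_noise_sd": config.obs_noise_sd,
        }
    if n_floored:
        logger.info("floored %d negative synthetic counts at 0", n_floored)
    return frame, truth


def generate_panel(config: SyntheticConfig) -> SyntheticPanel:
    """Generate a full synthetic panel (populations + admissions + truth)."""
    rng = np.random.default_rng(config.seed)
    populations = generate_populations(config, rng)
    frame, truth = generate_admissions(populations, config, rng)
    columns = ["area_id", "year", "admissions"] + list(COVARIATE_COLUMNS) + ["is_projected"]
    return SyntheticPanel(frame=frame[columns], truth=truth, config=config)
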