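"""Area metadata, aggregation of predictive draws across geographies, crude rates."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .predict import ForecastResult, summarize_draws

__all__ = [
    "AreaGeography",
    "RateSummary",
    "crude_rate",
    "rate_change",
    "aggregate_draws",
    "tier_rate_table",
]

logger = logging.getLogger(__name__)

TIERS = ("region", "supergroup", "group", "subgroup")


class UnmappedAreaError(KeyError):
    """Raised when forecast areas are missing from the geography lookup."""


@dataclass(frozen=True)
class AreaGeography:
    """One area's position in the region / ONS-cluster hierarchy."""

    area_id: str
    region: str
    supergroup: str
    group: str
    subgroup: str

    def __post_init__(self) -> None:
        for name in ("area_id",) + TIERS:
            if not getattr(self, name):
                raise ValueError(f"geography field {name!r} must be non-empty")

    def tier_value(self, tier: str) -> str:
        if tier == "national":
            return "national"
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        return getattr(self, tier)


@dataclass(frozen=True)
class RateSummary:
    """Crude-rate summary for one geographic unit."""

    level: str
    unit: str
    count: float
    population: float
    rate_per_1000: float
    rate_change_per_1000: float | None = None


def crude_rate(count: float, population: float) -> float:
    """Events per 1,000 persons: ``1000 * count / population``."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return 1000.0 * count / population


def rate_change(
    count_now: float, pop_now: float, count_base: float, pop_base: float
) -> tuple[float, float]:
    """Absolute (per 1,000) and percent change in crude rate vs a baseline year."""
    rate_now = crude_rate(count_now, pop_now)
    rate_base = crude_rate(count_base, pop_base)
    return rate_now - rate_base, 100.0 * (rate_now / rate_base - 1.0)


def aggregate_draws(
    forecasts: dict[str, ForecastResult],
    geography: dict[str, AreaGeography],
    level: str,
) -> dict[str, ForecastResult]:
    """Sum member-area predictive draws within each unit of a tier.

    Per-unit draws are element-wise sums across member areas (areas treated
    as independent; draw g of the sum is a coherent joint sample), and all
    summaries are recomputed on the summed draws.  ``level`` may be any tier
    name or ``"national"``.
    """
    missing = sorted(set(forecasts) - set(geography)) if level != "national" else []
    if missing:
        raise UnmappedAreaError(f"areas missing from geography lookup: {missing}")

    groups: dict[str, list[str]] = {}
    for area_id in forecasts:
        unit = (
            "national" if level == "national" else geography[area_id].tier_value(level)
        )
        groups.setdefault(unit, []).append(area_id)

    reference = next(iter(forecasts.values()))
    out: dict[str, ForecastResult] = {}
    for unit, members in sorted(groups.items()):
        shapes = {forecasts[a].predictive_draws.shape for a in members}
        if len(shapes) != 1:
            raise ValueError(f"members of {unit!r} have mismatched draw shapes")
        years = reference.horizon_years
        for a in members:
            if not np.array_equal(forecasts[a].horizon_years, years):
                raise ValueError("mismatched horizon years across areas")
        total = np.sum([forecasts[a].predictive_draws for a in members], axis=0)
        pip = np.mean([forecasts[a].inclusion_probabilities for a in members], axis=0)
        out[unit] = summarize_draws(total, years, pip)
    return out


def tier_rate_table(
    counts: dict[str, float],
    populations: dict[str, float],
    base_counts: dict[str, float] | None = None,
    base_populations: dict[str, float] | None = None,
    level: str = "region",
) -> list[RateSummary]:
    """Crude-rate rows per unit, optionally with change vs a baseline year."""
    rows = []
    for unit in sorted(counts):
        rate = crude_rate(counts[unit], populations[unit])
        change = None
        if base_counts is not None and base_populations is not None:
            change, _ = rate_change(
                counts[unit], populations[unit], base_counts[unit], base_populations[unit]
            )
        rows.append(
            RateSummary(
                level=level,
                unit=unit,
                count=counts[unit],
                population=populations[unit],
                rate_per_1000=rate,
                rate_change_per_1000=change,
            )
        )
    return rows


def drop_excluded(rows, exclusions) -> list:
    """Drop records whose area id is in the exclusion list, logging the count."""
    excluded = {r for r in rows if getattr(r, "area_id", r) in set(exclusions)}
    if excluded:
        logger.info("excluded %d areas: %s", len(excluded), sorted(
            getattr(r, "area_id", r) for r in excluded))
    return [r for r in rows if r not in excluded]
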