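"""Shared fixtures: small synthetic panels and pre-fitted models.

Everything is generated programmatically; no stored fixture files.
"""

from __future__ import annotations

import numpy as np
import pytest

import levelcast as lc
from levelcast.synthetic_data import COVARIATE_COLUMNS

#: synthetic settings under which the model is well identified: stratum
#: trajectories decorrelated by wiggle, per-coefficient signal-to-noise 5
RECOVERY_KWARGS = dict(
    true_coefficients=(0, 0, 3.0, 0, 0, -2.0, 0, 0, 0),
    obs_noise_sd=15.0,
    level_innovation_sd=2.0,
    target_snr=5.0,
    population_trend_range=(-200.0, 200.0),
    population_wiggle_sd=4000.0,
)

TRUE_NONZERO = (2, 5)


def area_arrays(panel, area_id, n_train=None):
    """Training response / design arrays for one synthetic area."""
    sub = panel.frame[
        (panel.frame.area_id == area_id) & (~panel.frame.is_projected)
    ].sort_values("year")
    y = sub["admissions"].to_numpy(dtype=float)
    x = sub[list(COVARIATE_COLUMNS)].to_numpy(dtype=float) / 1000.0
    if n_train is not None:
        return y[:n_train], x[:n_train], y[n_train:], x[n_train:]
    return y, x


@pytest.fixture(scope="session")
def recovery_panel():
    cfg = lc.SyntheticConfig(n_areas=5, seed=42, **RECOVERY_KWARGS)
    return lc.generate_panel(cfg)


@pytest.fixture(scope="session")
def fitted_area(recovery_panel):
    """One area fitted with a mid-length chain, reused across test modules."""
    y, x = area_arrays(recovery_panel, "A000")
    config = lc.FitConfig(n_iterations=5000, seed=11)
    draws = lc.fit_model(y, x, config, covariate_names=list(COVARIATE_COLUMNS))
    return {"draws": draws, "y": y, "x": x, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)
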