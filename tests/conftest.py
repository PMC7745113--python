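"""Shared fixtures: expensive campaign runs are session-scoped."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import flowtube as ft
from flowtube.campaign import run_campaign
from flowtube.doe import DesignSpec, build_design
from flowtube.pseudoexperiment import generate_campaign
from flowtube.reactor import GridOptions, solve_reactor

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return ft.default_config()


@pytest.fixture(scope="session")
def full_design(cfg):
    return build_design(
        DesignSpec(factors=cfg.factor_levels(), design_kind="full_2k")
    )


@pytest.fixture(scope="session")
def fractional_design(cfg):
    return build_design(
        DesignSpec(
            factors=cfg.factor_levels(), design_kind="fractional_2k_minus_1"
        )
    )


@pytest.fixture(scope="session")
def full_campaign(cfg, full_design) -> pd.DataFrame:
    """32-run in-silico factorial campaign on the campaign grid."""
    return run_campaign(full_design, cfg)


@pytest.fixture(scope="session")
def synthetic_campaign(cfg, fractional_design) -> pd.DataFrame:
    """48-record triplicate pseudo-experimental campaign (seed 1)."""
    return generate_campaign(fractional_design, pipeline=cfg, seed=1)


@pytest.fixture(scope="session")
def fractional_predictions(cfg, fractional_design) -> pd.DataFrame:
    """Clean (unbiased, impurity-free) simulator runs of the half fraction."""
    return run_campaign(fractional_design, cfg)


@pytest.fixture(scope="session")
def startup_run(cfg):
    """Default-grid transient at the long-residence, hot corner.

    5 m x 1 mm tube, 0.1 mL/min, 40 degC bath, chi = 0.95; integrated to
    five residence times with field snapshots every 0.1 tau.
    """
    case = ft.ReactorCase.from_natural(5, 1.0, 0.1, 40.0, 0.95)
    sol, res = solve_reactor(
        case.geometry, case.operating, case.grid, cfg.system,
        thermal=cfg.thermal,
    )
    return sol, res


@pytest.fixture(scope="session")
def campaign_grid_fast():
    """Coarse grid for quick single-run solver checks."""
    return GridOptions(
        n_radial=16,
        n_axial=100,
        end_time_multiple=3.0,
        snapshot_interval_multiple=0.0,
    )
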