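"""Synthetic pseudo-experimental campaign.

The bench campaign this emulates measured triplicate HPLC yields over the
half-fraction design.  Three deviation channels distinguish it from the
clean simulator output, each a documented stand-in for an effect whose true
magnitude was never measured:

* an impurity side-channel — consecutive first-order, Arrhenius-activated
  consumption of the product, tuned so the impurity stays below ~0.5% at
  short residence times but reaches the low single digits of percent at the
  longest, hottest conditions;
* imperfect bath heating — the effective wall temperature relaxes a few
  percent of the way from the bath set point towards ambient (plus a small
  additional drift along the coil), so heated runs are slightly cooler and
  chilled runs slightly warmer than nominal;
* multiplicative lognormal replicate noise (HPLC area ratios are positive
  and roughly scale-proportional), mean-preserving with a configurable CV.

A fixed seed reproduces the campaign bit for bit.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from .campaign import case_from_row
from .config import PipelineConfig, SyntheticConfig, default_config
from .reactor import FirstOrderDecay, ReactorCase, SolverError, solve_reactor

__all__ = [
    "PseudoExperimentConfig",
    "impurity_decay",
    "wall_temperature_profile",
    "impurity_fraction",
    "generate_campaign",
]

logger = logging.getLogger(__name__)

# The synthetic-experiment block of the pipeline configuration is the
# campaign configuration; re-export under the name used in this module.
PseudoExperimentConfig = SyntheticConfig


def impurity_decay(config: SyntheticConfig) -> FirstOrderDecay:
    """Arrhenius parameters of the product-consuming side channel."""
    return FirstOrderDecay(
        pre_exponential=config.impurity_pre_exponential_per_min,
        activation_energy=config.impurity_activation_energy_J_mol,
    )


def wall_temperature_profile(
    case: ReactorCase, config: SyntheticConfig
) -> np.ndarray:
    """Imperfect-bath wall temperature along the tube (n_axial,).

    wall(z) = T_bath + bias + (pull + gradient * z/L) * (T_ambient - T_bath)
    """
    nz = case.grid.n_axial
    z_frac = (np.arange(nz) + 0.5) / nz
    t_bath = case.operating.bath_temperature
    pull = config.ambient_pull_fraction + config.gradient_fraction * z_frac
    return t_bath + config.bath_bias_K + pull * (config.ambient_K - t_bath)


def _solve_condition(
    row,
    pipeline: PipelineConfig,
    config: SyntheticConfig,
):
    case = case_from_row(
        row, pipeline.campaign_grid, pipeline.inlet_temperature
    )
    wall = wall_temperature_profile(case, config)
    _, res = solve_reactor(
        case.geometry,
        case.operating,
        case.grid,
        pipeline.system,
        thermal=pipeline.thermal,
        wall_temperature=wall,
        impurity=impurity_decay(config),
    )
    return res


def impurity_fraction(
    row,
    config: SyntheticConfig | None = None,
    pipeline: PipelineConfig | None = None,
) -> float:
    """Impurity yield (% of limiting reagent) at one design condition."""
    pipeline = pipeline or default_config()
    config = config or pipeline.synthetic
    if config.impurity_pre_exponential_per_min == 0.0:
        return 0.0
    res = _solve_condition(row, pipeline, config)
    return res.impurity_yield_percent


def generate_campaign(
    design: pd.DataFrame,
    config: SyntheticConfig | None = None,
    pipeline: PipelineConfig | None = None,
    seed: int = 0,
    simulator: Callable | None = None,
) -> pd.DataFrame:
    """Triplicate pseudo-experimental records for every design row.

    Each distinct condition is solved once (with the biased wall profile
    and the impurity channel); replicate records then apply independent
    mean-preserving lognormal noise draws.  ``simulator(row) ->
    (yield_pct, impurity_pct, tau_min)`` may replace the reactor solver
    (used in tests).  A failed condition is flagged and excluded; the
    campaign continues.
    """
    pipeline = pipeline or default_config()
    config = config or pipeline.synthetic
    rng = np.random.default_rng(seed)
    cv = config.replicate_noise_cv
    sigma = np.sqrt(np.log1p(cv**2))
    records = []
    for _, row in design.iterrows():
        rec_base = dict(row)
        try:
            if simulator is not None:
                y, imp, tau_min = simulator(row)
            else:
                res = _solve_condition(row, pipeline, config)
                y, imp = res.outlet_yield_percent, res.impurity_yield_percent
                tau_min = res.residence_time / 60.0
        except SolverError as exc:
            logger.error("condition %s failed: %s", dict(row), exc)
            rec = dict(rec_base)
            rec.update({"replicate": 0, "yield_pct": np.nan, "failed": True})
            records.append(rec)
            continue
        for rep in range(1, config.replicates + 1):
            draw = rng.standard_normal()
            noise = (
                np.exp(sigma * draw - 0.5 * sigma**2) if sigma > 0 else 1.0
            )
            rec = dict(rec_base)
            rec.update(
                {
                    "replicate": rep,
                    "tau_min": tau_min,
                    "yield_pct": y * noise,
                    "impurity_pct": imp,
                    "noise_draw": draw,
                    "seed": seed,
                    "failed": False,
                }
            )
            records.append(rec)
    out = pd.DataFrame(records)
    return out[~out["failed"]].reset_index(drop=True).drop(columns=["failed"])
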