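"""Parity analysis: simulated versus observed yields.

A parity plot of predicted against observed yield over the screening
campaign splits into two linear regimes around a crossover yield: the
simulator underestimates low yields and overestimates high ones.  This
module fits ordinary least squares lines (free intercepts) to the two
segments, and summarises absolute errors against residence time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ParityResult", "parity_analysis", "error_vs_residence_time"]


@dataclass
class ParityResult:
    """Two-segment parity fit of predicted vs observed yields."""

    pairs: pd.DataFrame  # predicted, observed, difference, tau_min
    crossover: float  # observed-yield split point, %
    slope_low: float
    intercept_low: float
    slope_high: float
    intercept_high: float

    @property
    def differences(self) -> np.ndarray:
        return self.pairs["difference"].to_numpy()


def _segment_fit(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """OLS line pred = slope*obs + intercept; NaN slope if < 2 points.

    Pairs are sorted before the fit so the result is bit-identical under
    any permutation of the input order.
    """
    if len(obs) < 2:
        return float("nan"), float("nan")
    order = np.lexsort((pred, obs))
    slope, intercept = np.polyfit(obs[order], pred[order], 1)
    return float(slope), float(intercept)


def parity_analysis(
    predicted,
    observed,
    crossover: float = 20.0,
    residence_time_min=None,
) -> ParityResult:
    """Split pairs at the observed-yield crossover and fit a line per side.

    ``predicted`` and ``observed`` are per-condition percent yields over
    the same condition set (observed typically a replicate mean);
    differences are predicted - observed.  A segment with fewer than two
    points gets an undefined (NaN) slope rather than an error.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must align one-to-one")
    if pred.size < 2:
        raise ValueError("need at least two (predicted, observed) pairs")
    tau = (
        np.asarray(residence_time_min, dtype=float)
        if residence_time_min is not None
        else np.full(pred.shape, np.nan)
    )
    pairs = pd.DataFrame(
        {
            "predicted": pred,
            "observed": obs,
            "difference": pred - obs,
            "tau_min": tau,
        }
    )
    low = obs < crossover
    slope_low, int_low = _segment_fit(obs[low], pred[low])
    slope_high, int_high = _segment_fit(obs[~low], pred[~low])
    return ParityResult(
        pairs=pairs,
        crossover=crossover,
        slope_low=slope_low,
        intercept_low=int_low,
        slope_high=slope_high,
        intercept_high=int_high,
    )


def error_vs_residence_time(
    result: ParityResult,
    low_tau_min: float = 5.0,
    high_tau_min: float = 8.0,
) -> tuple[pd.DataFrame, dict]:
    """Absolute yield error per condition sorted by residence time.

    Returns the sorted (tau_min, abs_error) table and a summary dict with
    the smallest |error| among short residence times (< ``low_tau_min``)
    and the largest among long ones (> ``high_tau_min``); a bin with no
    conditions is simply absent from the summary.
    """
    pairs = result.pairs
    if pairs["tau_min"].isna().any():
        raise ValueError("residence times must be attached to every pair")
    table = (
        pairs.assign(abs_error=pairs["difference"].abs())
        .sort_values("tau_min")
        .reset_index(drop=True)[
            ["tau_min", "abs_error", "predicted", "observed", "difference"]
        ]
    )
    summary: dict[str, float] = {}
    short = table[table["tau_min"] < low_tau_min]
    if len(short):
        summary["min_abs_error_short_tau"] = float(short["abs_error"].min())
    long_ = table[table["tau_min"] > high_tau_min]
    if len(long_):
        summary["max_abs_error_long_tau"] = float(long_["abs_error"].max())
    return table, summary
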