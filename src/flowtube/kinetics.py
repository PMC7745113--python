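"""Second-order Arrhenius reaction kinetics and Arrhenius-plot fitting.

The condensation of methyl 4-methoxyacetoacetate (M4MAA) with
N,N-dimethylformamide dimethyl acetal (DMF-DMA) to the enamine intermediate
is modelled as an irreversible reaction that is first order in each reactant:

    rate = k(T) * cA * cB,      k(T) = A * exp(-Ea / (R T))

The rate constant is carried in the bench units it is usually reported in
(L mol^-1 min^-1); :func:`rate_constant_si` converts to m^3 mol^-1 s^-1 for
the transport solver.  The closed-form integrated rate law gives batch
conversion for equal and unequal feeds, and :class:`ArrheniusModel` recovers
(A, Ea) from isothermal concentration-time series the way an Arrhenius plot
does: estimate k at each temperature, then regress ln k on 1/T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GAS_CONSTANT",
    "KineticParams",
    "DEFAULT_KINETICS",
    "DEFAULT_STOICHIOMETRY",
    "BatchRun",
    "ArrheniusModel",
    "ArrheniusResults",
    "InsufficientDataError",
    "rate_constant",
    "rate_constant_si",
    "batch_conversion",
    "batch_concentrations",
    "fit_arrhenius",
]

logger = logging.getLogger(__name__)

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

#: A + B -> P + 2 MeOH.  Methanol is carried so the mass balance closes.
DEFAULT_STOICHIOMETRY: Mapping[str, float] = {
    "M4MAA": -1.0,
    "DMFDMA": -1.0,
    "Enamine": 1.0,
    "MeOH": 2.0,
}

# Conversion from L mol^-1 min^-1 to m^3 mol^-1 s^-1.
_L_MIN_TO_SI = 1e-3 / 60.0


@dataclass(frozen=True)
class KineticParams:
    """Arrhenius parameters and stoichiometry of the enamine formation.

    Parameters
    ----------
    pre_exponential : float
        Pre-exponential factor A, L mol^-1 min^-1.
    activation_energy : float
        Activation energy Ea, J mol^-1.
    heat_of_reaction : float
        Molar reaction enthalpy, J mol^-1 (negative = exothermic).  The
        default magnitude is a documented placeholder used only by the
        energy balance; no screening conclusion depends on it.
    stoichiometry : mapping
        Species name -> signed stoichiometric coefficient.
    """

    pre_exponential: float = 2.00e8
    activation_energy: float = 57930.0
    gas_constant: float = GAS_CONSTANT
    heat_of_reaction: float = -50000.0
    stoichiometry: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOICHIOMETRY)
    )

    def __post_init__(self) -> None:
        if self.pre_exponential < 0.0:
            raise ValueError("pre-exponential factor must be non-negative")
        if self.activation_energy < 0.0:
            raise ValueError("activation energy must be non-negative")
        reactants = [c for c in self.stoichiometry.values() if c < 0]
        if reactants and sorted(reactants) != [-1.0, -1.0]:
            raise ValueError(
                "the two reactants must each have stoichiometric coefficient -1"
            )


#: Kinetics of the enamine condensation used throughout as the default.
DEFAULT_KINETICS = KineticParams()


def rate_constant(T, params: KineticParams = DEFAULT_KINETICS):
    """Second-order rate constant k(T) in L mol^-1 min^-1."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0.0):
        raise ValueError("temperature must be positive (kelvin)")
    k = params.pre_exponential * np.exp(
        -params.activation_energy / (params.gas_constant * T)
    )
    return float(k) if np.ndim(k) == 0 else k


def rate_constant_si(T, params: KineticParams = DEFAULT_KINETICS):
    """Rate constant in SI units, m^3 mol^-1 s^-1."""
    return rate_constant(T, params) * _L_MIN_TO_SI


def _extent(c_a0: float, c_b0: float, k, t):
    """Reaction extent x(t) (mol L^-1) of dx/dt = k (a-x)(b-x), x(0)=0.

    Uses the closed form ``x = a b expm1(d k t) / (d + b expm1(d k t))`` with
    d = b - a, which limits smoothly onto the equal-feed law as d -> 0.
    """
    a, b = float(c_a0), float(c_b0)
    d = b - a
    kt = np.asarray(k, dtype=float) * np.asarray(t, dtype=float)
    if d == 0.0:  # equal feed: the closed form has a removable singularity
        return a * a * kt / (1.0 + a * kt)
    with np.errstate(over="ignore", invalid="ignore"):
        e = np.expm1(np.clip(d * kt, -700.0, 700.0))
        x = a * b * e / (d + b * e)
    # kt == 0 gives 0/0 -> 0 extent
    x = np.where(kt == 0.0, 0.0, x)
    return x


def batch_conversion(c_a0: float, c_b0: float, k, t):
    """Fractional conversion of the limiting reagent in an isothermal batch.

    Parameters are the initial concentrations (mol L^-1), the rate constant
    (L mol^-1 min^-1) and the batch time (min); ``k*t`` only enters as a
    product so any consistent unit pair works.
    """
    if c_a0 <= 0.0 or c_b0 <= 0.0:
        raise ValueError("initial concentrations must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("batch time must be non-negative")
    x = _extent(c_a0, c_b0, k, t_arr)
    conv = x / min(c_a0, c_b0)
    return float(conv) if np.ndim(t) == 0 and np.ndim(k) == 0 else conv


def batch_concentrations(c_a0: float, c_b0: float, k, t):
    """(cA, cB) concentration pair along an isothermal batch trajectory."""
    x = _extent(c_a0, c_b0, k, np.asarray(t, dtype=float))
    return c_a0 - x, c_b0 - x


class InsufficientDataError(ValueError):
    """Not enough distinct temperatures for an Arrhenius regression."""


@dataclass(frozen=True)
class BatchRun:
    """One isothermal batch concentration-time series.

    ``concentration`` tracks reactant A (the monitored species, mol L^-1);
    ``c_b0`` is the co-reactant's initial concentration and defaults to the
    first concentration point (equal feed).
    """

    temperature: float  # K
    times: np.ndarray  # min
    concentration: np.ndarray  # mol L^-1
    c_b0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "concentration", np.asarray(self.concentration, dtype=float)
        )
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must have equal length")
        if np.any(self.concentration <= 0.0):
            raise ValueError("concentrations must be strictly positive")


@dataclass(frozen=True)
class ArrheniusResults:
    """Estimates from an Arrhenius regression of per-temperature rate fits."""

    pre_exponential: float  # L mol^-1 min^-1
    activation_energy: float  # J mol^-1
    r_squared: float
    slope: float
    intercept: float
    rate_constants: Mapping[float, float]  # T (K) -> k (L mol^-1 min^-1)

    def summary(self) -> str:
        lines = [
            "Arrhenius regression (ln k vs 1/T)",
            f"  Ea = {self.activation_energy / 1000.0:.3f} kJ/mol",
            f"  A  = {self.pre_exponential:.4g} L/mol/min",
            f"  R^2 = {self.r_squared:.6f}",
            "  per-temperature rate constants:",
        ]
        for T in sorted(self.rate_constants):
            lines.append(f"    T = {T:7.2f} K   k = {self.rate_constants[T]:.6g}")
        return "\n".join(lines)


class ArrheniusModel:
    """Arrhenius parameter recovery from isothermal batch runs.

    Each run's rate constant is estimated by least squares on the integrated
    second-order law, then ln k is regressed on 1/T; the slope gives
    ``-Ea/R`` and the intercept ``ln A``.
    """

    def __init__(self, runs: Sequence[BatchRun]):
        self.runs = list(runs)
        temps = {round(r.temperature, 9) for r in self.runs}
        if len(temps) < 2:
            raise InsufficientDataError(
                "at least two distinct temperatures are required"
            )

    @staticmethod
    def _fit_rate_constant(run: BatchRun) -> float:
        c = run.concentration
        if np.any(np.diff(c) > 1e-12):
            warnings.warn(
                "non-monotone concentration series; rate fit proceeds",
                stacklevel=3,
            )
        c_a0 = float(c[0])
        c_b0 = float(run.c_b0) if run.c_b0 is not None else c_a0
        # crude initial guess from the equal-feed linearisation
        with np.errstate(divide="ignore"):
            slope0 = np.polyfit(run.times, 1.0 / c, 1)[0]
        k0 = max(float(slope0), 1e-12)

        def model(t, log_k):
            ca, _ = batch_concentrations(c_a0, c_b0, np.exp(log_k), t)
            return ca

        popt, _ = optimize.curve_fit(
            model, run.times, c, p0=[np.log(k0)], maxfev=10000
        )
        return float(np.exp(popt[0]))

    def fit(self) -> ArrheniusResults:
        temps, ks = [], []
        for run in self.runs:
            temps.append(run.temperature)
            ks.append(self._fit_rate_constant(run))
        temps_arr = np.asarray(temps)
        ks_arr = np.asarray(ks)
        reg = stats.linregress(1.0 / temps_arr, np.log(ks_arr))
        ea = -reg.slope * GAS_CONSTANT
        return ArrheniusResults(
            pre_exponential=float(np.exp(reg.intercept)),
            activation_energy=float(ea),
            r_squared=float(reg.rvalue**2),
            slope=float(reg.slope),
            intercept=float(reg.intercept),
            rate_constants=dict(zip(temps, ks)),
        )


def fit_arrhenius(runs: Sequence[BatchRun]) -> ArrheniusResults:
    """Functional wrapper around :class:`ArrheniusModel`."""
    return ArrheniusModel(runs).fit()


def synthetic_batch_runs(
    temperatures_c: Sequence[float] = (10.0, 20.0, 30.0, 40.0),
    c_a0: float = 1.0,
    c_b0: float = 1.3,
    n_points: int = 25,
    params: KineticParams = DEFAULT_KINETICS,
) -> list[BatchRun]:
    """Noiseless batch series generated from the integrated rate law.

    Batch duration at each temperature is scaled to reach ~70% conversion so
    every series is informative for the rate fit.
    """
    runs = []
    for tc in temperatures_c:
        T = tc + 273.15
        k = rate_constant(T, params)
        c_min = min(c_a0, c_b0)
        # time to ~70% conversion of the limiting reagent (equal-feed scale)
        t_end = 0.7 / (1 - 0.7) / (k * c_min)
        t = np.linspace(0.0, t_end, n_points)
        ca, _ = batch_concentrations(c_a0, c_b0, k, t)
        runs.append(BatchRun(temperature=T, times=t, concentration=ca, c_b0=c_b0))
    return runs
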