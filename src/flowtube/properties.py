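"""Species and mixture thermophysical property rules.

The reacting stream is a multicomponent organic liquid.  Mixture properties
are built from pure-component values with the standard ideal-solution rules:

* density — ideal specific-volume additivity, ``1/rho_mix = sum_i w_i / rho_i``
  (harmonic mean in mass fractions);
* viscosity — log-linear (Arrhenius/Grunberg-Nissan with no interaction
  term), ``mu_mix = exp(sum_i n_i ln mu_i)`` in mole fractions;
* heat capacity — mass-specific, ``cp_mix = sum_i cp_i w_i / M_i`` where
  ``cp_i`` is the molar heat capacity.

All quantities are SI: kg m^-3, Pa s, J mol^-1 K^-1, kg mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SpeciesProps",
    "MixtureState",
    "InvalidPropertyError",
    "mixture_density",
    "mixture_viscosity",
    "mixture_heat_capacity",
]


class InvalidPropertyError(ValueError):
    """A species property is outside its physical domain."""


@dataclass(frozen=True)
class SpeciesProps:
    """Pure-component properties of one liquid species.

    Parameters
    ----------
    name : str
        Species identifier.
    density : float
        Mass density, kg m^-3.
    viscosity : float
        Dynamic viscosity, Pa s.
    molar_heat_capacity : float
        Molar isobaric heat capacity, J mol^-1 K^-1.
    molar_mass : float
        Molar mass, kg mol^-1.
    """

    name: str
    density: float
    viscosity: float
    molar_heat_capacity: float
    molar_mass: float

    def __post_init__(self) -> None:
        for attr in ("density", "viscosity", "molar_heat_capacity", "molar_mass"):
            value = getattr(self, attr)
            if not np.isfinite(value) or value <= 0.0:
                raise InvalidPropertyError(
                    f"{self.name}.{attr} must be strictly positive, got {value!r}"
                )


_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MixtureState:
    """Composition (and temperature) of a liquid mixture.

    Mass and mole fractions are stored redundantly; ``from_mass_fractions`` /
    ``from_mole_fractions`` derive one from the other given molar masses so
    the two stay mutually consistent.
    """

    mass_fractions: Mapping[str, float]
    mole_fractions: Mapping[str, float]
    temperature: float = 298.15
    _validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if not self._validate:
            return
        for label, fracs in (
            ("mass", self.mass_fractions),
            ("mole", self.mole_fractions),
        ):
            vals = np.asarray(list(fracs.values()), dtype=float)
            if vals.size == 0:
                raise ValueError(f"empty {label}-fraction mapping")
            if np.any(vals < -_FRACTION_TOL) or np.any(vals > 1.0 + _FRACTION_TOL):
                raise ValueError(f"{label} fractions must lie in [0, 1]: {fracs}")
            if abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError(
                    f"{label} fractions must sum to 1, got {vals.sum():.12g}"
                )
        if set(self.mass_fractions) != set(self.mole_fractions):
            raise ValueError("mass and mole fraction keys differ")

    @classmethod
    def from_mass_fractions(
        cls,
        mass_fractions: Mapping[str, float],
        props: Mapping[str, SpeciesProps],
        temperature: float = 298.15,
    ) -> "MixtureState":
        w = {k: float(v) for k, v in mass_fractions.items()}
        moles = {k: w[k] / props[k].molar_mass for k in w}
        total = sum(moles.values())
        n = {k: v / total for k, v in moles.items()}
        return cls(w, n, temperature)

    @classmethod
    def from_mole_fractions(
        cls,
        mole_fractions: Mapping[str, float],
        props: Mapping[str, SpeciesProps],
        temperature: float = 298.15,
    ) -> "MixtureState":
        n = {k: float(v) for k, v in mole_fractions.items()}
        masses = {k: n[k] * props[k].molar_mass for k in n}
        total = sum(masses.values())
        w = {k: v / total for k, v in masses.items()}
        return cls(w, n, temperature)


def _gather(
    state_fractions: Mapping[str, float],
    props: Mapping[str, SpeciesProps],
    attr: str,
) -> tuple[np.ndarray, np.ndarray]:
    names = list(state_fractions)
    fr = np.asarray([state_fractions[k] for k in names], dtype=float)
    vals = np.empty_like(fr)
    for i, name in enumerate(names):
        p = props[name]
        vals[i] = getattr(p, attr)
    if np.any(vals <= 0.0):
        raise InvalidPropertyError(f"non-positive {attr} among {names}")
    return fr, vals


def mixture_density(
    state: MixtureState, props: Mapping[str, SpeciesProps]
) -> float:
    """Mixture density from ideal specific-volume additivity, kg m^-3.

    ``1/rho = sum_i w_i / rho_i``; the result is bounded by the lightest and
    densest component.
    """
    w, rho = _gather(state.mass_fractions, props, "density")
    return float(1.0 / np.sum(w / rho))


def mixture_viscosity(
    state: MixtureState, props: Mapping[str, SpeciesProps]
) -> float:
    """Mole-fraction log-linear mixture viscosity, Pa s."""
    n, mu = _gather(state.mole_fractions, props, "viscosity")
    return float(np.exp(np.sum(n * np.log(mu))))


def mixture_heat_capacity(
    state: MixtureState, props: Mapping[str, SpeciesProps]
) -> float:
    """Mass-specific mixture heat capacity, J kg^-1 K^-1.

    ``cp = sum_i cp_molar_i * w_i / M_i``.
    """
    w, cp = _gather(state.mass_fractions, props, "molar_heat_capacity")
    _, M = _gather(state.mass_fractions, props, "molar_mass")
    return float(np.sum(cp * w / M))
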