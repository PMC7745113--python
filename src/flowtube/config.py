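"""Pipeline configuration: YAML schema, defaults and validation.

A configuration file has five blocks — ``species``, ``kinetics``,
``factors``, ``grid``/``campaign_grid``, ``thermal`` and ``synthetic`` —
documented in the packaged ``default_config.yaml``.  Values are converted
to SI once, here, so the numerical core never sees bench units.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .kinetics import KineticParams
from .properties import SpeciesProps
from .reactor import GridOptions, ReactionSystem, ThermalOptions

__all__ = [
    "PipelineConfig",
    "SyntheticConfig",
    "ConfigError",
    "load_config",
    "default_config",
]


class ConfigError(ValueError):
    """Configuration file failed validation."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the pseudo-experimental campaign (stand-ins).

    The impurity Arrhenius pair and the bath-imperfection terms are explicit
    modelling stand-ins for effects whose true magnitudes were never
    measured; they are tuned to the reported qualitative behaviour and
    documented as such.
    """

    replicates: int = 3
    replicate_noise_cv: float = 0.03
    bath_bias_K: float = 0.0
    ambient_pull_fraction: float = 0.05
    gradient_fraction: float = 0.01
    ambient_K: float = 293.15
    impurity_pre_exponential_per_min: float = 5.5e10
    impurity_activation_energy_J_mol: float = 80000.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.replicate_noise_cv < 0.0:
            raise ConfigError("replicate noise CV must be non-negative")
        if (
            self.impurity_pre_exponential_per_min < 0.0
            or self.impurity_activation_energy_J_mol < 0.0
        ):
            raise ConfigError("impurity parameters must be non-negative")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, SI-unit view of a configuration file."""

    system: ReactionSystem
    factors: Mapping[str, tuple[float, float]]
    grid: GridOptions
    campaign_grid: GridOptions
    thermal: ThermalOptions
    inlet_temperature: float
    synthetic: SyntheticConfig
    source_hash: str = ""

    def factor_levels(self) -> dict[str, tuple[float, float]]:
        return {k: tuple(v) for k, v in self.factors.items()}


_FACTOR_ORDER = ("L", "ID", "Q", "T", "chi")


def _grid_from_block(block: Mapping, defaults: GridOptions) -> GridOptions:
    return GridOptions(
        n_radial=int(block.get("n_radial", defaults.n_radial)),
        n_axial=int(block.get("n_axial", defaults.n_axial)),
        diffusivity=float(
            block.get("diffusivity_m2_s", defaults.diffusivity)
        ),
        end_time_multiple=float(
            block.get("end_time_multiple", defaults.end_time_multiple)
        ),
        steady_tolerance=float(
            block.get("steady_tolerance", defaults.steady_tolerance)
        ),
    )


def _parse(raw: Mapping, source_hash: str) -> PipelineConfig:
    try:
        species = {}
        for name, blk in raw["species"].items():
            species[name] = SpeciesProps(
                name=name,
                density=float(blk["density_kg_m3"]),
                viscosity=float(blk["viscosity_Pa_s"]),
                molar_heat_capacity=float(blk["molar_heat_capacity_J_mol_K"]),
                molar_mass=float(blk["molar_mass_kg_mol"]),
            )
        kin_blk = raw["kinetics"]
        kinetics = KineticParams(
            pre_exponential=float(kin_blk["pre_exponential_L_mol_min"]),
            activation_energy=float(kin_blk["activation_energy_J_mol"]),
            heat_of_reaction=float(kin_blk.get("heat_of_reaction_J_mol", -5e4)),
        )
        factors = {}
        for name in _FACTOR_ORDER:
            lo, hi = raw["factors"][name]
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise ConfigError(f"factor {name}: low must be < high")
            factors[name] = (lo, hi)
        grid = _grid_from_block(raw.get("grid", {}), GridOptions())
        campaign_grid = _grid_from_block(
            raw.get("campaign_grid", {}),
            GridOptions(n_radial=24, n_axial=200, end_time_multiple=3.0),
        )
        thermal_blk = raw.get("thermal", {})
        thermal = ThermalOptions(
            conductivity=float(thermal_blk.get("conductivity_W_m_K", 0.15)),
            energy_on=bool(thermal_blk.get("energy_equation", True)),
        )
        inlet_t = float(thermal_blk.get("inlet_temperature_K", 295.15))
        syn_blk = dict(raw.get("synthetic", {}))
        imp = syn_blk.pop("impurity", {})
        synthetic = SyntheticConfig(
            replicates=int(syn_blk.get("replicates", 3)),
            replicate_noise_cv=float(syn_blk.get("replicate_noise_cv", 0.03)),
            bath_bias_K=float(syn_blk.get("bath_bias_K", 0.0)),
            ambient_pull_fraction=float(
                syn_blk.get("ambient_pull_fraction", 0.05)
            ),
            gradient_fraction=float(syn_blk.get("gradient_fraction", 0.01)),
            ambient_K=float(syn_blk.get("ambient_K", 293.15)),
            impurity_pre_exponential_per_min=float(
                imp.get("pre_exponential_per_min", 5.5e10)
            ),
            impurity_activation_energy_J_mol=float(
                imp.get("activation_energy_J_mol", 8.0e4)
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"missing configuration key: {exc}") from exc
    system = ReactionSystem(props=species, kinetics=kinetics)
    for required in (
        system.reactant_a,
        system.reactant_b,
        system.product,
        system.byproduct,
    ):
        if required not in species:
            raise ConfigError(f"species block missing {required!r}")
    return PipelineConfig(
        system=system,
        factors=factors,
        grid=grid,
        campaign_grid=campaign_grid,
        thermal=thermal,
        inlet_temperature=inlet_t,
        synthetic=synthetic,
        source_hash=source_hash,
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML configuration (packaged default if None)."""
    if path is None:
        text = (
            importlib.resources.files("flowtube")
            .joinpath("default_config.yaml")
            .read_text()
        )
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"configuration file not found: {p}")
        text = p.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    digest = hashlib.sha256(text.encode()).hexdigest()[:12]
    return _parse(raw, digest)


def default_config() -> PipelineConfig:
    """The packaged default configuration."""
    return load_config(None)
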