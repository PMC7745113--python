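"""Transient 2-D axisymmetric laminar tube-reactor solver.

Model
-----
A straight tube of length L and inner diameter ID carries a fully developed
laminar (Poiseuille) flow.  Species transport obeys

    dc_i/dt + u(r) dc_i/dz = D (1/r d/dr (r dc_i/dr) + d2c_i/dz2) + nu_i k(T) cA cB

with u(r) = 2 u_mean (1 - (r/R)^2), and the energy balance is the analogous
advection-diffusion equation with volumetric source (-dH) k(T) cA cB and
thermal diffusivity alpha = k_th / (rho cp).  Boundary conditions: symmetry
at the axis, zero species flux and Dirichlet (bath) temperature at the wall,
Dirichlet inlet (perfectly premixed feed at the inlet temperature),
zero-gradient outflow.  The initial state holds a linear axial gradient of
the first reactant (full inlet strength at the inlet, zero at the outlet)
at the bath temperature, mimicking a freshly primed reactor, and the run
covers several residence times so the startup transient washes out.

Numerics
--------
Finite volumes in r (flux form with radial metrics), first-order upwind
advection plus central axial diffusion in z, and Lie splitting in time:
explicit advection / axial diffusion / reaction, implicit (backward-Euler)
radial diffusion solved as batched tridiagonal systems.  The time step is
set by the advective CFL, which at unit Courant number makes upwind
transport nearly exact; radial diffusion, the stiff direction, is
unconditionally stable.  The momentum equation is not solved: at Reynolds
numbers of order unity and nearly constant density the parabolic profile is
an excellent approximation and is imposed.

Outlet yield is the mixing-cup (flow-weighted) enamine molar flow divided
by the limiting-reagent inlet molar flow, i.e. what an outlet sample
measures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import xarray as xr
from scipy.linalg import solve_banded

from .kinetics import GAS_CONSTANT, KineticParams, rate_constant_si
from .properties import (
    MixtureState,
    SpeciesProps,
    mixture_density,
    mixture_heat_capacity,
    mixture_viscosity,
)

__all__ = [
    "ReactorGeometry",
    "OperatingPoint",
    "GridOptions",
    "ThermalOptions",
    "FirstOrderDecay",
    "ReactionSystem",
    "ReactorCase",
    "FieldSolution",
    "SimResult",
    "SolverError",
    "residence_time",
    "inlet_composition",
    "dimensionless_numbers",
    "solve_reactor",
    "diffusivity_sweep",
    "transient_profiles",
]

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Numerical failure of the transient solver."""


@dataclass(frozen=True)
class ReactorGeometry:
    """Tube geometry: length L (m) and inner diameter ID (m)."""

    length: float
    inner_diameter: float

    def __post_init__(self) -> None:
        if self.length <= 0.0 or self.inner_diameter <= 0.0:
            raise ValueError("length and inner diameter must be positive")
        if self.length / self.inner_diameter < 100.0:
            raise ValueError(
                "aspect ratio L/ID must be >= 100 for the slender-tube model"
            )

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class OperatingPoint:
    """Operating conditions of one reactor run.

    flow_rate is the total volumetric feed Q in m^3 s^-1, bath_temperature
    the water-bath set point (K), molar_ratio the DMF-DMA : M4MAA feed ratio
    chi, and inlet_temperature the (room-temperature) feed temperature.
    """

    flow_rate: float
    bath_temperature: float
    molar_ratio: float
    inlet_temperature: float = 295.15

    def __post_init__(self) -> None:
        if self.flow_rate <= 0.0:
            raise ValueError("flow rate must be positive")
        if self.molar_ratio <= 0.0:
            raise ValueError("molar ratio must be positive")
        for t in (self.bath_temperature, self.inlet_temperature):
            if not (250.0 <= t <= 400.0):
                raise ValueError(f"temperature {t} K outside the 250-400 K range")


@dataclass(frozen=True)
class GridOptions:
    """Numerical grid and run-length options."""

    n_radial: int = 32
    n_axial: int = 400
    diffusivity: float = 1.0e-9  # m^2 s^-1, isotropic species diffusivity
    end_time_multiple: float = 5.0  # run length in residence times
    steady_tolerance: float = 1.0e-2  # relative, for steady-state detection
    cfl: float = 0.9
    snapshot_interval_multiple: float = 0.1  # 0 disables field snapshots

    def __post_init__(self) -> None:
        if self.n_radial < 8:
            raise ValueError("n_radial must be >= 8")
        if self.n_axial < 50:
            raise ValueError("n_axial must be >= 50")
        if self.diffusivity <= 0.0:
            raise ValueError("diffusivity must be positive")
        if self.end_time_multiple <= 0.0 or self.cfl <= 0.0 or self.cfl > 1.0:
            raise ValueError("invalid time-stepping options")


@dataclass(frozen=True)
class ThermalOptions:
    """Energy-balance options.

    conductivity is the mixture thermal conductivity (W m^-1 K^-1, organic
    liquid scale); energy_on toggles the full energy balance versus an
    isothermal reactor held at the wall temperature.
    """

    conductivity: float = 0.15
    energy_on: bool = True


@dataclass(frozen=True)
class FirstOrderDecay:
    """Arrhenius first-order consumption channel (product -> impurity)."""

    pre_exponential: float  # min^-1
    activation_energy: float  # J mol^-1

    def rate_si(self, T):
        """First-order rate constant in s^-1."""
        return (
            self.pre_exponential
            / 60.0
            * np.exp(-self.activation_energy / (GAS_CONSTANT * np.asarray(T)))
        )


@dataclass(frozen=True)
class ReactionSystem:
    """Species set plus kinetics driving the reactor."""

    props: Mapping[str, SpeciesProps]
    kinetics: KineticParams
    reactant_a: str = "M4MAA"
    reactant_b: str = "DMFDMA"
    product: str = "Enamine"
    byproduct: str = "MeOH"

    @property
    def species_order(self) -> tuple[str, ...]:
        return (self.reactant_a, self.reactant_b, self.product, self.byproduct)


@dataclass(frozen=True)
class ReactorCase:
    """One design row: geometry, operating point and grid options."""

    geometry: ReactorGeometry
    operating: OperatingPoint
    grid: GridOptions = field(default_factory=GridOptions)

    @classmethod
    def from_natural(
        cls,
        length_m: float,
        inner_diameter_mm: float,
        flow_rate_ml_min: float,
        temperature_c: float,
        molar_ratio: float,
        grid: GridOptions | None = None,
        inlet_temperature: float = 295.15,
    ) -> "ReactorCase":
        """Build a case from bench units (m, mm, mL/min, degC)."""
        geom = ReactorGeometry(length_m, inner_diameter_mm * 1e-3)
        op = OperatingPoint(
            flow_rate=flow_rate_ml_min * 1e-6 / 60.0,
            bath_temperature=temperature_c + 273.15,
            molar_ratio=molar_ratio,
            inlet_temperature=inlet_temperature,
        )
        return cls(geom, op, grid or GridOptions())

    def natural(self) -> dict:
        return {
            "L_m": self.geometry.length,
            "ID_mm": self.geometry.inner_diameter * 1e3,
            "Q_mL_min": self.operating.flow_rate * 6e7,
            "T_C": self.operating.bath_temperature - 273.15,
            "chi": self.operating.molar_ratio,
        }


def residence_time(geom: ReactorGeometry, op: OperatingPoint) -> float:
    """Mean residence time tau = V / Q in seconds."""
    return geom.volume / op.flow_rate


@dataclass(frozen=True)
class InletComposition:
    """Premixed inlet stream derived from two neat reagent feeds."""

    concentrations: Mapping[str, float]  # mol m^-3 in the combined stream
    stream_flows: tuple[float, float]  # (Q1, Q2) in m^3 s^-1
    limiting: str
    mass_fractions: Mapping[str, float]


def inlet_composition(
    op: OperatingPoint, system: ReactionSystem
) -> InletComposition:
    """Mix two neat reagent streams at the molar feed ratio chi.

    Solves F1 = Q1 rho1/M1, F2 = Q2 rho2/M2, F2/F1 = chi and Q1 + Q2 = Q for
    the stream split, assuming ideal (volume-additive) mixing; returns the
    concentrations of the perfectly premixed combined stream.
    """
    a, b = system.reactant_a, system.reactant_b
    pa, pb = system.props[a], system.props[b]
    na = pa.density / pa.molar_mass  # neat molar density, mol m^-3
    nb = pb.density / pb.molar_mass
    chi = op.molar_ratio
    q1 = op.flow_rate / (1.0 + chi * na / nb)
    q2 = op.flow_rate - q1
    f1, f2 = q1 * na, q2 * nb
    conc = {a: f1 / op.flow_rate, b: f2 / op.flow_rate}
    limiting = b if f2 < f1 else a
    m1, m2 = q1 * pa.density, q2 * pb.density
    w = {a: m1 / (m1 + m2), b: m2 / (m1 + m2)}
    return InletComposition(conc, (q1, q2), limiting, w)


def dimensionless_numbers(
    geom: ReactorGeometry,
    op: OperatingPoint,
    density: float,
    viscosity: float,
    diffusivity: float,
) -> tuple[float, float]:
    """(Re, Pe) based on the mean velocity and the tube diameter."""
    u_mean = op.flow_rate / (math.pi * geom.radius**2)
    re = density * u_mean * geom.inner_diameter / viscosity
    pe = u_mean * geom.inner_diameter / diffusivity
    return re, pe


@dataclass
class SimResult:
    """Summary of one reactor simulation."""

    outlet_yield_percent: float
    impurity_yield_percent: float
    yield_vs_length: np.ndarray  # % at each axial node, final time
    yield_vs_time: np.ndarray  # (n_saved, 2): residence-time multiple, %
    reynolds: float
    peclet: float
    residence_time: float  # s
    steady_state_time_multiple: float
    steady_reached: bool
    conservation_error_percent: float
    case: ReactorCase

    def row(self) -> dict:
        """Flat record suitable for a runs CSV."""
        rec = self.case.natural()
        rec.update(
            {
                "yield_pct": self.outlet_yield_percent,
                "impurity_pct": self.impurity_yield_percent,
                "Re": self.reynolds,
                "Pe": self.peclet,
                "tau_min": self.residence_time / 60.0,
                "steady_multiple": self.steady_state_time_multiple,
            }
        )
        return rec


FieldSolution = xr.Dataset
"""Concentration/temperature fields on the (time, r, z) grid (xarray)."""


def _feed_mixture_properties(
    system: ReactionSystem, inlet: InletComposition
) -> tuple[float, float, float]:
    """(rho, mu, cp_mass) of the combined feed stream."""
    state = MixtureState.from_mass_fractions(
        dict(inlet.mass_fractions), system.props
    )
    rho = mixture_density(state, system.props)
    mu = mixture_viscosity(state, system.props)
    cp = mixture_heat_capacity(state, system.props)
    return rho, mu, cp


def _radial_banded(
    coef: float, a: np.ndarray, b: np.ndarray, dt: float, wall_coef: float = 0.0
) -> np.ndarray:
    """Backward-Euler banded matrix (I - dt*coef*L_r) for solve_banded."""
    n = a.size
    ab = np.zeros((3, n))
    diag = 1.0 + dt * coef * (a + b)
    diag[-1] += dt * coef * wall_coef
    ab[1] = diag
    ab[0, 1:] = -dt * coef * b[:-1]
    ab[2, :-1] = -dt * coef * a[1:]
    return ab


def solve_reactor(
    geom: ReactorGeometry,
    op: OperatingPoint,
    grid: GridOptions,
    system: ReactionSystem,
    thermal: ThermalOptions | None = None,
    wall_temperature: np.ndarray | float | None = None,
    impurity: FirstOrderDecay | None = None,
) -> tuple[FieldSolution, SimResult]:
    """Integrate the transient reactor to ``end_time_multiple`` residence times.

    Parameters
    ----------
    wall_temperature : float or (n_axial,) array, optional
        Wall (bath) temperature profile along the tube; defaults to the
        operating bath temperature everywhere.  Used by the synthetic
        experiment to emulate imperfect bath heating.
    impurity : FirstOrderDecay, optional
        Consecutive first-order consumption of the product into a tracked
        impurity species.

    Returns
    -------
    (FieldSolution, SimResult)
    """
    thermal = thermal or ThermalOptions()
    tau = residence_time(geom, op)
    inlet = inlet_composition(op, system)
    rho, mu, cp_mass = _feed_mixture_properties(system, inlet)
    re, pe = dimensionless_numbers(geom, op, rho, mu, grid.diffusivity)

    names = list(system.species_order)
    if impurity is not None:
        names.append("Impurity")
    ns = len(names)
    ia, ib, ip = 0, 1, 2  # A, B, product indices in species_order
    c_in = np.zeros(ns)
    c_in[ia] = inlet.concentrations[system.reactant_a]
    c_in[ib] = inlet.concentrations[system.reactant_b]
    c_lim = c_in[ia] if inlet.limiting == system.reactant_a else c_in[ib]

    nr, nz = grid.n_radial, grid.n_axial
    R = geom.radius
    dr, dz = R / nr, geom.length / nz
    r_c = (np.arange(nr) + 0.5) * dr
    r_f = np.arange(nr + 1) * dr
    z_c = (np.arange(nz) + 0.5) * dz
    u_mean = op.flow_rate / (math.pi * R**2)
    u = 2.0 * u_mean * (1.0 - (r_c / R) ** 2)
    weights = u * r_c  # mixing-cup weights (annulus flow per unit dr)
    wsum = weights.sum()

    if wall_temperature is None:
        t_wall = np.full(nz, op.bath_temperature)
    else:
        t_wall = np.broadcast_to(
            np.asarray(wall_temperature, dtype=float), (nz,)
        ).copy()

    alpha = thermal.conductivity / (rho * cp_mass)
    d_species = grid.diffusivity
    k_si = rate_constant_si  # alias
    params = system.kinetics
    dh = params.heat_of_reaction
    stoich = params.stoichiometry
    nu = np.array([stoich.get(n, 0.0) for n in names])
    nu[ia], nu[ib], nu[ip] = -1.0, -1.0, 1.0

    # --- time step ------------------------------------------------------
    t_end = grid.end_time_multiple * tau
    dt_adv = grid.cfl * dz / u.max()
    dt_ax = 0.4 * dz**2 / max(d_species, alpha if thermal.energy_on else 0.0)
    t_hot = max(op.bath_temperature, op.inlet_temperature) + 2.0
    k_hot = float(k_si(t_hot, params))
    dt_react = 0.1 / max(k_hot * max(c_in[ia], c_in[ib]), 1e-30)
    dt = min(dt_adv, dt_ax, dt_react)
    n_steps = max(1, int(math.ceil(t_end / dt)))
    dt = t_end / n_steps
    logger.debug(
        "solver: tau=%.3g s, dt=%.3g s, %d steps, grid %dx%d",
        tau, dt, n_steps, nr, nz,
    )

    # --- radial diffusion operators ------------------------------------
    geo_a = r_f[:-1] / (r_c * dr**2)
    geo_b = r_f[1:] / (r_c * dr**2)
    geo_b_species = geo_b.copy()
    geo_b_species[-1] = 0.0  # zero wall flux for species
    ab_species = _radial_banded(d_species, geo_a, geo_b_species, dt)
    wall_coef = 2.0 * r_f[-1] / (r_c[-1] * dr**2)
    geo_b_temp = geo_b.copy()
    geo_b_temp[-1] = 0.0
    ab_temp = _radial_banded(alpha, geo_a, geo_b_temp, dt, wall_coef=wall_coef)
    t_wall_src = dt * alpha * wall_coef * t_wall  # (nz,) RHS addition

    # --- state ----------------------------------------------------------
    C = np.zeros((ns, nr, nz))
    C[ia] = c_in[ia] * (1.0 - z_c / geom.length)[None, :]
    T = np.tile(t_wall, (nr, 1)).astype(float)
    t_inlet = op.inlet_temperature if thermal.energy_on else t_wall[0]

    u_dt_dz = (dt / dz) * u[:, None]
    heat_coef = -dh / (rho * cp_mass)

    def outlet_yield(Carr):
        return 100.0 * float(weights @ Carr[ip, :, -1]) / (wsum * c_lim)

    snap_times: list[float] = []
    snap_C: list[np.ndarray] = []
    snap_T: list[np.ndarray] = []
    if grid.snapshot_interval_multiple > 0:
        snap_dt = grid.snapshot_interval_multiple * tau
        next_snap = 0.0
    else:
        snap_dt = math.inf
        next_snap = math.inf

    rec_every = max(1, n_steps // 2500)
    rec_t: list[float] = []
    rec_y: list[float] = []

    t_now = 0.0
    for step in range(n_steps + 1):
        # record / snapshot at the *current* state
        if step % rec_every == 0 or step == n_steps:
            rec_t.append(t_now)
            rec_y.append(outlet_yield(C))
        if t_now >= next_snap - 1e-9 * tau:
            snap_times.append(t_now)
            snap_C.append(C.copy())
            snap_T.append(T.copy())
            next_snap += snap_dt
        if step == n_steps:
            break

        # 1) advection (upwind; Dirichlet inlet ghost, outflow by upwinding)
        C_up = np.empty_like(C)
        C_up[:, :, 0] = c_in[:, None]
        C_up[:, :, 1:] = C[:, :, :-1]
        C -= u_dt_dz[None] * (C - C_up)
        if thermal.energy_on:
            T_up = np.empty_like(T)
            T_up[:, 0] = t_inlet
            T_up[:, 1:] = T[:, :-1]
            T = T - u_dt_dz * (T - T_up)

        # 2) axial diffusion (explicit central; inlet Dirichlet ghost,
        #    outlet zero-gradient)
        lap = np.empty_like(C)
        lap[:, :, 1:-1] = C[:, :, 2:] - 2.0 * C[:, :, 1:-1] + C[:, :, :-2]
        lap[:, :, 0] = C[:, :, 1] - 2.0 * C[:, :, 0] + c_in[:, None]
        lap[:, :, -1] = C[:, :, -2] - C[:, :, -1]
        C += (dt * d_species / dz**2) * lap
        if thermal.energy_on:
            lap_t = np.empty_like(T)
            lap_t[:, 1:-1] = T[:, 2:] - 2.0 * T[:, 1:-1] + T[:, :-2]
            lap_t[:, 0] = T[:, 1] - 2.0 * T[:, 0] + t_inlet
            lap_t[:, -1] = T[:, -2] - T[:, -1]
            T = T + (dt * alpha / dz**2) * lap_t

        # 3) reaction (+ optional impurity channel) and heat release
        k_field = k_si(T, params)
        rate = k_field * C[ia] * C[ib]
        C += (dt * rate)[None] * nu[:, None, None]
        if impurity is not None:
            dI = dt * impurity.rate_si(T) * C[ip]
            C[ip] -= dI
            C[-1] += dI
        if thermal.energy_on:
            T = T + dt * heat_coef * rate
        np.clip(C, 0.0, None, out=C)

        # 4) radial diffusion (implicit)
        rhs = C.transpose(1, 0, 2).reshape(nr, ns * nz)
        sol = solve_banded((1, 1), ab_species, rhs)
        C = sol.reshape(nr, ns, nz).transpose(1, 0, 2).copy()
        if thermal.energy_on:
            t_rhs = T.copy()
            t_rhs[-1, :] += t_wall_src  # Dirichlet wall enters the last row
            T = solve_banded((1, 1), ab_temp, t_rhs)

        t_now += dt
        if not np.all(np.isfinite(C[ip, :, -1])):
            raise SolverError(
                f"solver diverged at t={t_now:.3g}s "
                f"(grid {nr}x{nz}, dt={dt:.3g}s)"
            )

    # --- diagnostics -----------------------------------------------------
    rec_t_arr = np.asarray(rec_t)
    rec_y_arr = np.asarray(rec_y)
    y_final = rec_y_arr[-1]
    tol = grid.steady_tolerance
    scale = max(abs(y_final), 1e-12)
    ok = np.abs(rec_y_arr - y_final) <= tol * scale
    # earliest record after which the yield stays within tolerance
    idx = len(ok) - 1
    while idx > 0 and ok[idx - 1]:
        idx -= 1
    steady_multiple = rec_t_arr[idx] / tau
    steady_reached = steady_multiple <= grid.end_time_multiple - tol
    if not steady_reached:
        logger.warning(
            "steady tolerance not reached by %.1f residence times",
            grid.end_time_multiple,
        )

    ycum = 100.0 * (weights @ C[ip]) / (wsum * c_lim)
    lim_idx = ia if inlet.limiting == system.reactant_a else ib
    f_lim_in = wsum * c_lim
    f_lim_out = float(weights @ C[lim_idx, :, -1])
    f_p_out = float(weights @ C[ip, :, -1])
    f_i_out = float(weights @ C[-1, :, -1]) if impurity is not None else 0.0
    consumed = f_lim_in - f_lim_out
    produced = f_p_out + f_i_out
    cons_err = (
        100.0 * abs(consumed - produced) / max(abs(consumed), 1e-12 * f_lim_in)
    )

    result = SimResult(
        outlet_yield_percent=float(y_final),
        impurity_yield_percent=100.0 * f_i_out / f_lim_in,
        yield_vs_length=ycum,
        yield_vs_time=np.column_stack([rec_t_arr / tau, rec_y_arr]),
        reynolds=re,
        peclet=pe,
        residence_time=tau,
        steady_state_time_multiple=float(steady_multiple),
        steady_reached=bool(steady_reached),
        conservation_error_percent=float(cons_err),
        case=ReactorCase(geom, op, grid),
    )

    if snap_times:
        conc = xr.DataArray(
            np.asarray(snap_C).transpose(1, 0, 2, 3),
            dims=("species", "time", "r", "z"),
            coords={
                "species": names,
                "time": snap_times,
                "r": r_c,
                "z": z_c,
            },
        )
        temp = xr.DataArray(
            np.asarray(snap_T), dims=("time", "r", "z"),
            coords={"time": snap_times, "r": r_c, "z": z_c},
        )
    else:
        conc = xr.DataArray(
            C[:, None], dims=("species", "time", "r", "z"),
            coords={"species": names, "time": [t_now], "r": r_c, "z": z_c},
        )
        temp = xr.DataArray(
            T[None], dims=("time", "r", "z"),
            coords={"time": [t_now], "r": r_c, "z": z_c},
        )
    solution = xr.Dataset(
        {
            "concentration": conc,
            "temperature": temp,
            "axial_velocity": xr.DataArray(u, dims=("r",), coords={"r": r_c}),
        },
        attrs={
            "residence_time_s": tau,
            "limiting_inlet_concentration": c_lim,
            "product": system.product,
            "limiting": inlet.limiting,
        },
    )
    return solution, result


def transient_profiles(
    solution: FieldSolution, multiples: Sequence[float]
) -> dict[float, np.ndarray]:
    """Axial mixing-cup yield profiles at chosen residence-time multiples.

    Each requested multiple must lie within the simulated time range; the
    nearest stored snapshot is used.
    """
    tau = solution.attrs["residence_time_s"]
    times = np.asarray(solution["time"])
    c_lim = solution.attrs["limiting_inlet_concentration"]
    u = np.asarray(solution["axial_velocity"])
    r = np.asarray(solution["r"])
    w = u * r
    t_max = times.max()
    out: dict[float, np.ndarray] = {}
    for m in multiples:
        t_req = m * tau
        if t_req < -1e-9 or t_req > t_max * (1.0 + 1e-9):
            raise ValueError(
                f"requested time {m} tau outside simulated range "
                f"[0, {t_max / tau:.3g} tau]"
            )
        i = int(np.argmin(np.abs(times - t_req)))
        cp = np.asarray(
            solution["concentration"].sel(species=solution.attrs["product"]).isel(
                time=i
            )
        )
        out[float(m)] = 100.0 * (w @ cp) / (w.sum() * c_lim)
    return out


def diffusivity_sweep(
    geom: ReactorGeometry,
    op: OperatingPoint,
    grid: GridOptions,
    system: ReactionSystem,
    d_values: Sequence[float],
    thermal: ThermalOptions | None = None,
) -> tuple[dict[float, float], float]:
    """Outlet yields over a sweep of species diffusivities.

    Returns (yield-per-D mapping, max-min spread in percentage points).
    Solver failures for individual diffusivities are logged and skipped.
    """
    if len(d_values) < 1:
        raise ValueError("at least one diffusivity required")
    yields: dict[float, float] = {}
    for d in d_values:
        g = replace(grid, diffusivity=float(d), snapshot_interval_multiple=0.0)
        try:
            _, res = solve_reactor(geom, op, g, system, thermal=thermal)
        except SolverError as exc:  # pragma: no cover - defensive
            logger.error("diffusivity %.3g failed: %s", d, exc)
            continue
        yields[float(d)] = res.outlet_yield_percent
    vals = list(yields.values())
    spread = max(vals) - min(vals) if vals else math.nan
    return yields, spread
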