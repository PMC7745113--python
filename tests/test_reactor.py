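"""Axisymmetric reactor solver: analytics, limits and conservation."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import flowtube as ft
from flowtube.kinetics import KineticParams
from flowtube.reactor import (
    GridOptions,
    OperatingPoint,
    ReactorCase,
    ReactorGeometry,
    ThermalOptions,
    diffusivity_sweep,
    dimensionless_numbers,
    inlet_composition,
    residence_time,
    solve_reactor,
    transient_profiles,
)
from flowtube.reduced import pfr_yield


class TestResidenceTime:
    def test_longest_design_corner_is_39_3_minutes(self):
        case = ReactorCase.from_natural(5, 1.0, 0.1, 40, 0.95)
        tau_min = residence_time(case.geometry, case.operating) / 60.0
        assert tau_min == pytest.approx(39.3, abs=0.05)

    def test_smallest_corner_hand_value(self):
        case = ReactorCase.from_natural(1, 0.25, 1.0, 25, 1.0)
        tau_min = residence_time(case.geometry, case.operating) / 60.0
        assert tau_min == pytest.approx(0.0491, abs=2e-4)

    def test_inverse_proportionality_in_flow(self):
        g = ReactorGeometry(2.0, 0.5e-3)
        op1 = OperatingPoint(1e-9, 300.0, 1.0)
        op2 = OperatingPoint(2e-9, 300.0, 1.0)
        assert residence_time(g, op1) == pytest.approx(
            2.0 * residence_time(g, op2)
        )


class TestGeometryValidation:
    def test_aspect_ratio_floor(self):
        with pytest.raises(ValueError, match="aspect"):
            ReactorGeometry(0.01, 1e-3)

    def test_temperature_window(self):
        with pytest.raises(ValueError):
            OperatingPoint(1e-9, 500.0, 1.0)

    def test_grid_minimums(self):
        with pytest.raises(ValueError):
            GridOptions(n_radial=4)


class TestInletComposition:
    def test_symmetric_feed(self, cfg):
        """Equal densities/molar masses at chi=1 split the flow evenly."""
        from flowtube.properties import SpeciesProps
        from flowtube.reactor import ReactionSystem

        props = dict(cfg.system.props)
        props["M4MAA"] = SpeciesProps("M4MAA", 1000.0, 1e-3, 100.0, 0.1)
        props["DMFDMA"] = SpeciesProps("DMFDMA", 1000.0, 1e-3, 100.0, 0.1)
        system = ReactionSystem(props=props, kinetics=cfg.system.kinetics)
        op = OperatingPoint(1e-8, 300.0, 1.0)
        inl = inlet_composition(op, system)
        q1, q2 = inl.stream_flows
        assert q1 == pytest.approx(q2)
        assert inl.concentrations["M4MAA"] == pytest.approx(1000.0 / 0.1 / 2.0)

    def test_vanishing_ratio_limit(self, cfg):
        op = OperatingPoint(1e-8, 300.0, 1e-9)
        inl = inlet_composition(op, cfg.system)
        assert inl.stream_flows[1] == pytest.approx(0.0, abs=1e-15)
        assert inl.concentrations["DMFDMA"] == pytest.approx(0.0, abs=1e-3)

    def test_against_nonlinear_solver_oracle(self, cfg):
        """Stream split matches a brute-force solve of the flow/ratio
        system to 1e-10 relative."""
        op = OperatingPoint(1e-6 / 60.0, 300.0, 1.5)  # 1 mL/min
        system = cfg.system
        pa = system.props["M4MAA"]
        pb = system.props["DMFDMA"]

        def eqs(q):
            q1, q2 = q
            f1 = q1 * pa.density / pa.molar_mass
            f2 = q2 * pb.density / pb.molar_mass
            return [f2 - 1.5 * f1, q1 + q2 - op.flow_rate]

        q1_ref, q2_ref = fsolve(eqs, [op.flow_rate / 2] * 2, xtol=1e-14)
        inl = inlet_composition(op, system)
        assert inl.stream_flows[0] == pytest.approx(q1_ref, rel=1e-10)
        assert inl.stream_flows[1] == pytest.approx(q2_ref, rel=1e-10)
        assert inl.limiting == "M4MAA"  # excess DMF-DMA at chi = 1.5

    def test_invalid_ratio(self, cfg):
        with pytest.raises(ValueError):
            OperatingPoint(1e-8, 300.0, -1.0)


class TestDimensionlessNumbers:
    def test_peclet_hand_value(self):
        g = ReactorGeometry(1.0, 1e-3)
        op = OperatingPoint(1e-6 / 60.0, 300.0, 1.0)
        _, pe = dimensionless_numbers(g, op, 1000.0, 5e-3, 1e-9)
        assert pe == pytest.approx(2.12e4, rel=5e-3)

    def test_reynolds_hand_value(self):
        g = ReactorGeometry(1.0, 1e-3)
        op = OperatingPoint(1e-6 / 60.0, 300.0, 1.0)
        re, _ = dimensionless_numbers(g, op, 1000.0, 5e-3, 1e-9)
        assert re == pytest.approx(4.24, rel=5e-3)

    def test_diameter_scaling(self):
        op = OperatingPoint(1e-6 / 60.0, 300.0, 1.0)
        g1 = ReactorGeometry(1.0, 1e-3)
        g2 = ReactorGeometry(0.5, 0.5e-3)
        _, pe1 = dimensionless_numbers(g1, op, 1000.0, 1e-3, 1e-9)
        _, pe2 = dimensionless_numbers(g2, op, 1000.0, 1e-3, 1e-9)
        # halving ID at fixed Q: u x4, Pe = u*ID/D doubles
        assert pe2 == pytest.approx(2.0 * pe1, rel=1e-12)


class TestSolver:
    def test_no_reaction_limit(self, cfg, campaign_grid_fast):
        """With a zero pre-exponential the outlet yield is zero and the
        temperature field relaxes to the bath."""
        case = ReactorCase.from_natural(
            1, 1.0, 0.5, 40, 1.0, grid=campaign_grid_fast
        )
        from dataclasses import replace

        system = replace(cfg.system, kinetics=KineticParams(pre_exponential=0.0))
        sol, res = solve_reactor(
            case.geometry, case.operating, case.grid, system,
            thermal=cfg.thermal,
        )
        assert res.outlet_yield_percent == 0.0
        t_final = np.asarray(sol["temperature"].isel(time=-1))
        # beyond the short thermal entrance the tube sits at the bath
        z = np.asarray(sol["z"])
        assert np.allclose(t_final[:, z > 0.5], 313.15, atol=0.05)

    def test_well_mixed_limit_matches_plug_flow(self, cfg):
        """At D = 1e-6 m2/s (radial mixing time << tau), isothermal, the
        outlet matches the plug-flow oracle within one point."""
        grid = GridOptions(
            n_radial=16, n_axial=100, diffusivity=1e-6,
            end_time_multiple=3.0, snapshot_interval_multiple=0.0,
        )
        case = ReactorCase.from_natural(1, 1.0, 0.1, 40, 0.95, grid=grid)
        _, res = solve_reactor(
            case.geometry, case.operating, case.grid, cfg.system,
            thermal=ThermalOptions(energy_on=False),
        )
        inl = inlet_composition(case.operating, cfg.system)
        ca = inl.concentrations["M4MAA"] / 1000.0
        cb = inl.concentrations["DMFDMA"] / 1000.0
        k = ft.rate_constant(313.15)
        tau_min = res.residence_time / 60.0
        assert res.outlet_yield_percent == pytest.approx(
            pfr_yield(ca, cb, k, tau_min), abs=1.0
        )

    def test_grid_doubling_changes_yield_by_less_than_half_point(self, cfg):
        yields = {}
        for nr, nz in ((16, 100), (32, 200)):
            grid = GridOptions(
                n_radial=nr, n_axial=nz, end_time_multiple=3.0,
                snapshot_interval_multiple=0.0,
            )
            case = ReactorCase.from_natural(1, 1.0, 0.1, 40, 0.95, grid=grid)
            _, res = solve_reactor(
                case.geometry, case.operating, case.grid, cfg.system,
                thermal=cfg.thermal,
            )
            yields[(nr, nz)] = res.outlet_yield_percent
            assert res.conservation_error_percent < 0.5
        assert abs(yields[(16, 100)] - yields[(32, 200)]) < 0.5

    def test_diffusivity_sweep_degenerate_cases(self, cfg, campaign_grid_fast):
        case = ReactorCase.from_natural(
            1, 1.0, 1.0, 40, 1.0, grid=campaign_grid_fast
        )
        ys, spread = diffusivity_sweep(
            case.geometry, case.operating, case.grid, cfg.system, [1e-9],
            thermal=cfg.thermal,
        )
        assert spread == 0.0 and len(ys) == 1
        from dataclasses import replace

        system = replace(cfg.system, kinetics=KineticParams(pre_exponential=0.0))
        ys0, spread0 = diffusivity_sweep(
            case.geometry, case.operating, case.grid, system, [1e-9, 1e-10],
            thermal=cfg.thermal,
        )
        assert spread0 == 0.0
        assert all(v == 0.0 for v in ys0.values())


class TestTransients:
    def test_initial_snapshot_has_no_product(self, startup_run):
        sol, _ = startup_run
        profiles = transient_profiles(sol, [0.0])
        assert np.allclose(profiles[0.0], 0.0)

    def test_final_snapshot_equals_steady_profile(self, startup_run):
        sol, res = startup_run
        profiles = transient_profiles(sol, [5.0])
        assert profiles[5.0][-1] == pytest.approx(
            res.outlet_yield_percent, rel=1e-2
        )
        # steady axial yield profile is nondecreasing
        assert np.all(np.diff(res.yield_vs_length) > -1e-9)

    def test_profiles_nondecreasing_towards_steady(self, startup_run):
        sol, _ = startup_run
        profiles = transient_profiles(sol, [1.0, 5.0])
        assert np.all(profiles[5.0] - profiles[1.0] > -1e-6)

    def test_out_of_range_time_rejected(self, startup_run):
        sol, _ = startup_run
        with pytest.raises(ValueError, match="outside"):
            transient_profiles(sol, [7.0])

    def test_thermal_entrance_is_short(self, startup_run):
        """Room-temperature feed equilibrates with the bath well before
        0.5 m in the low-velocity case: radial spread < 0.5 K beyond."""
        sol, _ = startup_run
        t_final = np.asarray(sol["temperature"].isel(time=-1))
        z = np.asarray(sol["z"])
        spread = t_final[:, z > 0.5].max(axis=0) - t_final[:, z > 0.5].min(
            axis=0
        )
        assert spread.max() < 0.5

    def test_species_conservation_at_steady_state(self, startup_run):
        _, res = startup_run
        assert res.conservation_error_percent < 0.5

    def test_velocity_profile_is_poiseuille(self, startup_run):
        sol, _ = startup_run
        u = np.asarray(sol["axial_velocity"])
        r = np.asarray(sol["r"])
        assert np.all(u > 0.0)
        u_mean_expected = (0.1e-6 / 60.0) / (np.pi * (0.5e-3) ** 2)
        assert u.max() == pytest.approx(2.0 * u_mean_expected, rel=1e-2)
        assert np.all(np.diff(u) < 0.0)  # monotone decay towards the wall
        del r
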