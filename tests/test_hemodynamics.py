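"""Boundary-condition formulas and the Navier–Stokes solver."""

import numpy as np
import pytest

from hemoshear.hemodynamics import (BloodProperties, BoundaryConditionSet,
                                    CharacteristicScales, SolverConfig,
                                    boundary_flux, check_mass_conservation,
                                    inflow_rate, inlet_flow_rate,
                                    mean_inlet_velocity, outflow_rates, reynolds,
                                    solve_flow, total_and_outlet_resistance,
                                    MEAN_VELOCITY_WEIGHTS_LITERAL)
from hemoshear.meshing import BOUNDARY_INLET, BOUNDARY_OUTLET, tetrahedralize
from hemoshear.synthetic_vessels import (UltrasoundMeasurement, make_centerline,
                                         make_vessel_surface)

from conftest import TUBE_LENGTH, TUBE_RADIUS, reynolds_to_q


class TestBoundaryConditionFormulas:
    def test_mean_velocity_default_weights(self):
        m = UltrasoundMeasurement("a", 0.6, 0.3, 0.003)
        assert mean_inlet_velocity(m) == pytest.approx(0.4)

    def test_mean_velocity_identity_when_weights_sum_to_one(self):
        m = UltrasoundMeasurement("a", 0.7, 0.7, 0.003)
        assert mean_inlet_velocity(m, (0.25, 0.75)) == pytest.approx(0.7)

    def test_mean_velocity_literal_weights(self):
        m = UltrasoundMeasurement("a", 0.6, 0.3, 0.003)
        assert mean_inlet_velocity(m, MEAN_VELOCITY_WEIGHTS_LITERAL) == pytest.approx(0.5)

    def test_flow_rate_hand_arithmetic(self):
        a, q = inlet_flow_rate(0.4, 0.003)
        assert a == pytest.approx(2.827e-5, rel=1e-3)
        assert q == pytest.approx(1.131e-5, rel=1e-3)

    def test_zero_velocity_zero_flow(self):
        _, q = inlet_flow_rate(0.0, 0.003)
        assert q == 0.0

    def test_doubled_area_convention_is_exactly_twice(self):
        a1, q1 = inlet_flow_rate(0.4, 0.003, "pi_r2")
        a2, q2 = inlet_flow_rate(0.4, 0.003, "paper_2pi_r2")
        assert a2 == pytest.approx(2 * a1) and q2 == pytest.approx(2 * q1)

    def test_total_resistance_division(self):
        r_total, r_out = total_and_outlet_resistance(12000.0, 1.0e-5, [1e-5])
        assert r_total == pytest.approx(1.2e9)
        assert r_out[0] == pytest.approx(1.2e9)  # single outlet takes it all

    def test_two_equal_outlets_parallel_identity(self):
        r_total, r_out = total_and_outlet_resistance(12000.0, 1.0e-5, [2e-5, 2e-5])
        assert r_out[0] == pytest.approx(2 * r_total)
        assert r_out[1] == pytest.approx(2 * r_total)

    def test_parallel_combination_reproduces_total(self):
        rng = np.random.default_rng(2)
        areas = rng.uniform(1e-6, 5e-5, size=4)
        r_total, r_out = total_and_outlet_resistance(10000.0, 8e-6, areas)
        assert 1.0 / np.sum(1.0 / np.asarray(r_out)) == pytest.approx(r_total)

    def test_zero_flow_rejected(self):
        with pytest.raises(ZeroDivisionError):
            total_and_outlet_resistance(12000.0, 0.0, [1e-5])

    def test_from_measurement_wiring(self):
        m = UltrasoundMeasurement("carotid_left", 0.6, 0.3, 0.003)
        bc = BoundaryConditionSet.from_measurement(m, 12000.0)
        assert bc.v_in == pytest.approx(0.4)
        assert bc.q_in == pytest.approx(0.4 * np.pi * 0.003**2)
        assert bc.r_total == pytest.approx(12000.0 / bc.q_in)


class TestReynolds:
    def test_default_constants(self, blood):
        re, laminar = reynolds(blood, CharacteristicScales())
        assert re == pytest.approx(726.857, rel=1e-4)
        assert laminar

    def test_zero_velocity_zero_re(self, blood):
        re, _ = reynolds(blood, CharacteristicScales(v_char=0.0))
        assert re == 0.0

    def test_linearity_in_velocity(self, blood):
        r1, _ = reynolds(blood, CharacteristicScales(v_char=0.2))
        r2, _ = reynolds(blood, CharacteristicScales(v_char=0.4))
        assert r2 == pytest.approx(2 * r1)

    def test_turbulent_flag_above_threshold(self, blood):
        re, laminar = reynolds(blood, CharacteristicScales(D=0.05, v_char=1.0))
        assert re > 2300 and not laminar


class TestSolveFlow:
    def test_zero_inflow_gives_zero_state(self, coarse_mesh, blood):
        bc = BoundaryConditionSet(q_in=0.0)
        sol = solve_flow(coarse_mesh, bc, blood, SolverConfig(mode="steady"))
        assert sol.converged
        assert np.all(sol.final_velocity == 0.0)
        assert np.ptp(sol.final_pressure) == 0.0

    def test_poiseuille_centerline_velocity(self, coarse_mesh, coarse_solution):
        sol, bc = coarse_solution
        i = np.argmin(np.linalg.norm(coarse_mesh.nodes
                                     - [TUBE_LENGTH / 2, 0, 0], axis=1))
        expected = 2 * bc.q_in / (np.pi * TUBE_RADIUS**2)
        # coarse 12-gon cross-section: generous band; the production-scale
        # tolerance is exercised in the acceptance suite
        assert sol.final_velocity[i, 0] == pytest.approx(expected, rel=0.10)
        assert abs(sol.final_velocity[i, 1]) < 0.02 * expected

    def test_mass_conservation_discrete_exact(self, coarse_mesh, coarse_solution):
        sol, _ = coarse_solution
        assert check_mass_conservation(sol, coarse_mesh) <= 1e-3

    def test_prescribed_inflow_matches_q_in(self, coarse_mesh, coarse_solution):
        sol, bc = coarse_solution
        assert inflow_rate(coarse_mesh, sol.final_velocity) == pytest.approx(bc.q_in)

    def test_outlet_circuit_identity(self, coarse_mesh, coarse_solution):
        sol, bc = coarse_solution
        q_out = outflow_rates(coarse_mesh, sol.final_velocity)[0]
        outlet_nodes = np.unique(coarse_mesh.boundary_faces[
            coarse_mesh.faces_with_label(BOUNDARY_OUTLET)])
        p_out = sol.final_pressure[outlet_nodes].mean()
        assert p_out == pytest.approx(bc.r_out[0] * q_out, rel=0.01)

    def test_energy_sanity_pressure_drops_downstream(self, coarse_mesh, coarse_solution):
        sol, _ = coarse_solution
        inlet_nodes = np.unique(coarse_mesh.boundary_faces[
            coarse_mesh.faces_with_label(BOUNDARY_INLET)])
        outlet_nodes = np.unique(coarse_mesh.boundary_faces[
            coarse_mesh.faces_with_label(BOUNDARY_OUTLET)])
        assert (sol.final_pressure[inlet_nodes].mean()
                > sol.final_pressure[outlet_nodes].mean())

    def test_stokes_mode_is_exactly_linear(self, coarse_mesh, blood):
        cfg = SolverConfig(mode="steady", convection=False)
        q = reynolds_to_q(50, TUBE_RADIUS, blood)
        u1 = solve_flow(coarse_mesh, BoundaryConditionSet(q_in=q), blood, cfg).final_velocity
        u2 = solve_flow(coarse_mesh, BoundaryConditionSet(q_in=2 * q), blood, cfg).final_velocity
        assert np.allclose(u2, 2 * u1, rtol=1e-10, atol=1e-14)

    def test_analytic_divergence_free_field_balances(self, coarse_mesh):
        # exact Poiseuille sampled at the nodes: discrete in/out fluxes agree
        rad = np.linalg.norm(coarse_mesh.nodes[:, 1:], axis=1)
        u = np.zeros((len(coarse_mesh.nodes), 3))
        u[:, 0] = 1.0 - (rad / TUBE_RADIUS) ** 2
        q_in = -boundary_flux(coarse_mesh, u, BOUNDARY_INLET)
        q_out = boundary_flux(coarse_mesh, u, BOUNDARY_OUTLET)
        assert q_out == pytest.approx(q_in, rel=1e-9)


@pytest.fixture(scope="module")
def tiny(blood):
    cl = make_centerline("straight", 0.008)
    vessel = make_vessel_surface(cl, 0.001)
    mesh = tetrahedralize(vessel, 5.0e-4, near_wall_factor=0.5)
    return mesh, reynolds_to_q(60, 0.001, blood)


class TestTransient:
    def test_backward_euler_reaches_steady_state(self, tiny, blood):
        mesh, q = tiny
        bc = BoundaryConditionSet(q_in=q, r_out=[0.0])
        cfg = SolverConfig(mode="transient", dt=0.01, t_end=2.0)
        sol = solve_flow(mesh, bc, blood, cfg)
        assert sol.converged
        assert sol.times[-1] < 2.0  # steady well before the horizon
        assert check_mass_conservation(sol, mesh) <= 1e-3

    def test_steady_state_independent_of_dt(self, tiny, blood):
        mesh, q = tiny
        bc = BoundaryConditionSet(q_in=q, r_out=[0.0])
        finals = []
        for dt in (0.01, 0.005):
            cfg = SolverConfig(mode="transient", dt=dt, t_end=2.0, steady_tol=1e-5)
            finals.append(solve_flow(mesh, bc, blood, cfg).final_velocity)
        diff = np.linalg.norm(finals[0] - finals[1]) / np.linalg.norm(finals[1])
        assert diff < 1e-3

    def test_transient_matches_steady_solver(self, tiny, blood):
        mesh, q = tiny
        bc = BoundaryConditionSet(q_in=q, r_out=[0.0])
        u_t = solve_flow(mesh, bc, blood,
                         SolverConfig(mode="transient", dt=0.01, t_end=2.0,
                                      steady_tol=1e-5)).final_velocity
        u_s = solve_flow(mesh, bc, blood, SolverConfig(mode="steady")).final_velocity
        assert np.linalg.norm(u_t - u_s) / np.linalg.norm(u_s) < 1e-2

    def test_pulsatile_waveform_modulates_inflow(self, tiny, blood):
        mesh, q = tiny
        bc = BoundaryConditionSet(q_in=q, r_out=[0.0], waveform="pulsatile",
                                  pulse_amplitude=0.5, pulse_period=0.4)
        cfg = SolverConfig(mode="transient", dt=0.02, t_end=0.4, save_every=1)
        sol = solve_flow(mesh, bc, blood, cfg)
        rates = [inflow_rate(mesh, sol.velocity[k]) for k in range(1, len(sol.times))]
        assert max(rates) > 1.2 * q and min(rates) < 0.8 * q


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0}, {"tol_linear": 2.0}, {"tol_nonlinear": 0.0}, {"mode": "warp"},
    ])
    def test_bad_solver_config(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)

    def test_bad_properties(self):
        with pytest.raises(ValueError):
            BloodProperties(rho=-1.0)

    def test_bc_validation(self):
        with pytest.raises(ValueError):
            BoundaryConditionSet(q_in=-1.0)
        with pytest.raises(ValueError):
            BoundaryConditionSet(q_in=1.0, waveform="square")
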