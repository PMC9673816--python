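"""Finite-volume transport-reaction solver: conservation, analytic limits, flow."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erf

from glucolux.kinetics import KineticParams, SpeciesState, lifetime, o2_in_unit, reaction_rates
from glucolux.rd_solver import (
    REGIONS,
    Mesh2D,
    RDSolver,
    TransportParams,
    build_flowcell_mesh,
    poiseuille_flow,
    steady_state,
)


def _closed_box(ny, nx, region="tissue", dx=2e-5, dy=2e-5):
    mesh = Mesh2D(
        region=np.full((ny, nx), REGIONS[region], dtype=np.int8),
        dx=dx, dy=dy,
        bc={e: ("zero_flux",) for e in ("left", "right", "top", "bottom")},
    )
    return mesh


class TestFlowcellMesh:
    def test_sensor_area_with_and_without_fillet(self):
        m0 = build_flowcell_mesh(fillet_radius_mm=0.0)
        a0 = (m0.region == REGIONS["sensor_enzymatic"]).sum() * 0.05**2
        assert a0 == pytest.approx(4.0 * 0.5, abs=1e-9)
        m1 = build_flowcell_mesh(fillet_radius_mm=0.1)
        a1 = (m1.region == REGIONS["sensor_enzymatic"]).sum() * 0.05**2
        analytic = 2.0 - 2 * (1 - np.pi / 4) * 0.1**2
        assert a1 == pytest.approx(analytic, abs=2 * 0.05**2)
        assert a1 < a0

    def test_sensor_is_centered(self):
        m = build_flowcell_mesh()
        cols = np.where((m.region == REGIONS["sensor_enzymatic"]).any(axis=0))[0]
        left_margin = cols.min() * 0.05
        right_margin = 7.6 - (cols.max() + 1) * 0.05
        assert left_margin == pytest.approx(1.8, abs=0.05)
        assert left_margin == pytest.approx(right_margin, abs=0.05)

    def test_oversized_sensor_rejected(self):
        with pytest.raises(ValueError):
            build_flowcell_mesh(sensor_length_mm=8.0)


class TestPoiseuilleFlow:
    def test_inlet_centerline_is_1p5_mean(self):
        mesh = build_flowcell_mesh()
        flow = poiseuille_flow(mesh, 0.009)
        assert flow.u_face[:, 0].max() == pytest.approx(1.5 * 0.009, rel=0.01)

    def test_flux_is_conserved_along_the_channel(self):
        mesh = build_flowcell_mesh()
        flow = poiseuille_flow(mesh, 0.009)
        fluxes = flow.u_face.sum(axis=0) * mesh.dy
        assert np.allclose(fluxes, fluxes[0], rtol=1e-3)

    def test_divergence_free_and_walls_closed(self):
        mesh = build_flowcell_mesh()
        flow = poiseuille_flow(mesh, 0.009)
        assert np.abs(flow.v_face[-1, :]).max() < 1e-12  # top wall closed
        div = (flow.u_face[:, 1:] - flow.u_face[:, :-1]) / mesh.dx + (
            flow.v_face[1:, :] - flow.v_face[:-1, :]
        ) / mesh.dy
        assert np.abs(div).max() < 1e-9

    def test_zero_mean_velocity_gives_zero_field(self):
        mesh = build_flowcell_mesh()
        flow = poiseuille_flow(mesh, 0.0)
        assert not flow.u_face.any() and not flow.v_face.any()


class TestAdvance:
    def test_mass_conservation_closed_box(self):
        mesh = _closed_box(8, 40)
        solver = RDSolver(mesh, kinetics=KineticParams(Et=0.0), dt=1.0,
                          init={"G": 0.0, "O2": 0.0})
        rng = np.random.default_rng(3)
        solver.state.G = rng.uniform(0.5, 2.0, mesh.shape)
        m0 = solver.total_mass("G")
        for _ in range(200):
            solver.step()
        assert abs(solver.total_mass("G") - m0) / m0 < 1e-10

    def test_step_diffusion_matches_erf_profile(self):
        # 1-D diffusion of a concentration step: c(x,t) = c0/2 erfc(x/2sqrt(Dt))
        D = 2.64e-10
        mesh = _closed_box(3, 200)  # 4 mm long, dx = 20 um
        solver = RDSolver(mesh, transport=TransportParams(DG=(D,) * 5, DO2=(1.5e-9,) * 5),
                          kinetics=KineticParams(Et=0.0), dt=0.25)
        x = (np.arange(200) + 0.5) * mesh.dx
        x0 = 100 * mesh.dx
        solver.state.G = np.where(x < x0, 1.0, 0.0)[None, :].repeat(3, axis=0)
        t_end = 200.0
        for _ in range(int(t_end / solver.dt)):
            solver.step()
        analytic = 0.5 * (1.0 - erf((x - x0) / (2 * np.sqrt(D * t_end))))
        err = np.abs(solver.state.G[1] - analytic)
        # exclude wall-affected ends
        assert err[20:-20].max() < 0.01

    def test_uniform_state_matches_well_mixed_ode(self):
        # a single zero-flux enzymatic cell must follow the 0-D network
        mesh = _closed_box(1, 1, region="sensor_enzymatic")
        kin = KineticParams()
        solver = RDSolver(mesh, kinetics=kin, dt=0.002, init={"G": 2.78, "O2": 0.009})
        t_end = 1.0
        for _ in range(int(t_end / solver.dt)):
            solver.step()

        def rhs(t, y):
            d = reaction_rates(SpeciesState(*np.maximum(y, 0.0)), kin)
            return [d.G, d.O2, d.E, d.Eprime, d.X1, d.X2]

        sol = solve_ivp(rhs, (0, t_end), [2.78, 0.009, kin.Et, 0, 0, 0],
                        method="Radau", rtol=1e-10, atol=1e-12)
        ref = sol.y[:, -1]
        got = np.array([solver.state.G[0, 0], solver.state.O2[0, 0],
                        solver.state.E[0, 0], solver.state.Eprime[0, 0],
                        solver.state.X1[0, 0], solver.state.X2[0, 0]])
        assert np.allclose(got, ref, rtol=2e-2, atol=1e-6)

    def test_enzyme_conservation_through_stepping(self):
        mesh = _closed_box(2, 2, region="sensor_enzymatic")
        kin = KineticParams()
        solver = RDSolver(mesh, kinetics=kin, dt=0.5, init={"G": 5.55, "O2": 0.009})
        for _ in range(50):
            solver.step()
        total = solver.state.enzyme_total()
        assert np.allclose(total, kin.Et, rtol=1e-9)

    def test_no_enzyme_sensor_relaxes_to_boundary_oxygen(self):
        mesh = build_flowcell_mesh(dx_mm=0.1, dy_mm=0.1)
        flow = poiseuille_flow(mesh, 0.009)
        solver = RDSolver(mesh, kinetics=KineticParams(Et=0.0), flow=flow, dt=2.0,
                          init={"G": 0.0, "O2": 0.001})
        for _ in range(900):
            solver.step()
        enz = mesh.mask("sensor_enzymatic")
        assert solver.state.O2[enz].mean() == pytest.approx(0.009, rel=1e-3)
        expected_tau = lifetime(o2_in_unit(0.009, "uM"), solver.sv)
        assert solver.sensor_lifetime() == pytest.approx(expected_tau, rel=1e-3)

    def test_steady_state_independent_of_dt(self):
        # implicit path: the G=2.78 plateau lifetime is insensitive to dt
        taus = []
        for dt in (1.0, 4.0):
            mesh = build_flowcell_mesh(dx_mm=0.1, dy_mm=0.1,
                                       inlet={"G": 2.78, "O2": 0.009})
            flow = poiseuille_flow(mesh, 0.009)
            solver = RDSolver(mesh, flow=flow, dt=dt, init={"G": 2.78, "O2": 0.009})
            for _ in range(int(1200 / dt)):
                solver.step()
            taus.append(solver.sensor_lifetime())
        assert abs(taus[0] - taus[1]) / taus[0] < 0.005


class TestSteadyState:
    def test_all_dirichlet_no_reaction_is_uniform(self):
        mesh = _closed_box(10, 20)
        for e in ("left", "right", "top", "bottom"):
            mesh.bc[e] = ("dirichlet", {"G": 2.78, "O2": 0.009})
        G, O2, _ = steady_state(mesh, kinetics=KineticParams(Et=0.0))
        assert np.allclose(G, 2.78, rtol=1e-8)
        assert np.allclose(O2, 0.009, rtol=1e-8)

    def test_zeroth_order_sink_parabolic_depression(self):
        # tissue slab between two capillary planes: G(y) = Pw - R y (h-y) / 2D
        R, D, Pw = 0.027, 2.64e-10, 2.78
        h = 0.2e-3  # 0.2 mm: depression stays positive
        ny = 40
        mesh = Mesh2D(
            region=np.full((ny, 6), REGIONS["tissue"], dtype=np.int8),
            dx=h / ny, dy=h / ny,
            bc={
                "top": ("dirichlet", {"G": Pw, "O2": 0.009}),
                "bottom": ("dirichlet", {"G": Pw, "O2": 0.009}),
                "left": ("zero_flux",),
                "right": ("zero_flux",),
            },
        )
        G, _, _ = steady_state(mesh, kinetics=KineticParams(Et=0.0), sink_G=R,
                               transport=TransportParams(DG=(D,) * 5, DO2=(1.5e-9,) * 5))
        y = (np.arange(ny) + 0.5) * mesh.dy
        analytic = Pw - R * y * (h - y) / (2 * D)
        assert np.abs(G[:, 3] - analytic).max() / Pw < 0.01
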