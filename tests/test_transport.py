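"""Transport solver: boundary data, CSF drive, stepping, functionals."""

import numpy as np
import pytest

from tracermc import coefficients as co
from tracermc import transport as tr
from tracermc.geometry import GeometrySpec, build_surrogate_hierarchy


@pytest.fixture(scope="module")
def small_hier():
    """2-level surrogate with a 6-hour horizon (fast drive and solves)."""
    spec = GeometrySpec(dimension=2, n_levels=2)
    return build_surrogate_hierarchy(spec, dt_base=900.0, T=6 * 3600.0)


@pytest.fixture(scope="module")
def mean_drive(small_hier):
    mesh = small_hier.mesh(2)
    vdir = co.directional_velocity(mesh.points, co.Model1Params(), 2)
    return tr.precompute_csf_drive(small_hier, 1.2e-10, vdir, 0.0)


class TestBoundaryProfile:
    def test_half_on_the_front(self):
        p = tr.BoundaryParams()
        t = 1234.0
        x = np.array([[0.0, p.z0 + p.v_z * t]])
        assert tr.boundary_profile(t, x, p)[0] == pytest.approx(0.5)

    def test_saturates_to_one(self):
        p = tr.BoundaryParams()
        h = tr.boundary_profile(1e9, np.array([[0.0, 0.07]]), p)[0]
        assert 0.99 < h < 1.0

    def test_initial_value_at_equator(self):
        # t = 0, x3 = 0: h = 1/2 + arctan(-a(0 - z0))/pi with a z0 = -4
        p = tr.BoundaryParams()
        h = tr.boundary_profile(0.0, np.array([[0.0, 0.0]]), p)[0]
        assert h == pytest.approx(0.5 + np.arctan(-4.0) / np.pi, abs=1e-12)
        assert h == pytest.approx(0.0780, abs=5e-5)


class TestCsfInitial:
    def test_reference_value(self):
        assert tr.csf_initial() == pytest.approx(3.57, abs=5e-3)

    def test_proportionality(self):
        p = tr.BoundaryParams()
        double_v = tr.BoundaryParams(V_csf=2 * p.V_csf)
        assert tr.csf_initial(double_v) == pytest.approx(tr.csf_initial(p) / 2)


class TestCsfDrive:
    def test_balance_holds_to_machine_precision(self, small_hier, mean_drive):
        p = mean_drive.params
        assert np.abs(mean_drive.balance - p.n0).max() / p.n0 < 1e-12

    def test_initial_concentration(self, mean_drive):
        assert mean_drive.c_csf[0] == pytest.approx(tr.csf_initial())

    def test_without_drainage_sas_content_mirrors_brain_uptake(self, mean_drive):
        # r = 0: c_csf = (n0 - brain)/V and decreases while the brain fills
        p = mean_drive.params
        assert np.all(mean_drive.cumulative_drainage == 0)
        want = (p.n0 - mean_drive.brain_content) / p.V_csf
        assert np.allclose(mean_drive.c_csf, want, rtol=1e-12)
        # monotone nonincreasing once past the switch-on transient
        assert np.all(np.diff(mean_drive.c_csf[2:]) <= 1e-15)

    def test_drainage_accumulator_increases_with_sink(self, small_hier):
        mesh = small_hier.mesh(2)
        p2 = co.Model2Params(v_avg=1.7e-7)
        scale = co.calibrate_model2_scale(mesh, p2)
        v = p2.gamma_shape * scale * co.model2_profile(mesh.points, p2)
        drive = tr.precompute_csf_drive(small_hier, 1.2e-10, v, p2.r)
        assert np.all(np.diff(drive.cumulative_drainage) > 0)
        assert np.abs(drive.balance - drive.params.n0).max() / drive.params.n0 < 1e-12


class TestSolveTransport:
    def test_zero_boundary_data_keeps_zero_solution(self, small_hier, mean_drive):
        mesh = small_hier.mesh(1)
        drive0 = tr.CsfDrive(
            mean_drive.dt,
            np.zeros_like(mean_drive.c_csf),
            np.zeros_like(mean_drive.brain_content),
            np.zeros_like(mean_drive.cumulative_drainage),
            mean_drive.params,
        )
        sol = tr.solve_transport(
            mesh, small_hier.dt(1), 1.2e-10, np.zeros_like(mesh.points), 0.0,
            drive0, np.array([1800.0, 3600.0]),
        )
        assert np.all(sol.snapshots == 0)

    def test_heat_equation_relaxes_to_boundary_value(self):
        # constant Dirichlet value, no convection/drainage: c -> c0 uniformly
        spec = GeometrySpec(dimension=2, n_levels=1)
        h = build_surrogate_hierarchy(spec, dt_base=2 * 43200.0, T=40 * 86400.0)
        mesh = h.mesh(1)
        c0 = 2.5
        n = int(h.T / h.dt(1))
        drive = tr.CsfDrive(
            h.dt(1) / 4,
            np.full(4 * n + 1, c0),
            np.zeros(4 * n + 1),
            np.zeros(4 * n + 1),
            tr.BoundaryParams(z0=100.0),  # front far above: profile ~ 1
        )
        D_fast = 5e-8  # diffusive time L^2/D ~ 4 days << horizon
        sol = tr.solve_transport(
            mesh, h.dt(1), D_fast, np.zeros_like(mesh.points), 0.0,
            drive, np.array([h.T]), p=tr.BoundaryParams(z0=100.0),
        )
        assert np.allclose(sol.snapshots[-1], c0, rtol=1e-3)

    def test_misaligned_observation_times_rejected(self, small_hier, mean_drive):
        mesh = small_hier.mesh(1)
        with pytest.raises(tr.TransportError, match="multiples"):
            tr.solve_transport(
                mesh, small_hier.dt(1), 1.2e-10, np.zeros_like(mesh.points), 0.0,
                mean_drive, np.array([1000.0]),
            )

    def test_undershoot_shrinks_under_refinement(self):
        # the boundary undershoot of the lumped scheme at full-scale
        # coefficients (steep unresolved boundary layer) shrinks per level
        spec = GeometrySpec(dimension=2, n_levels=3)
        h = build_surrogate_hierarchy(spec)
        mesh_f = h.mesh(3)
        vdir_f = co.directional_velocity(mesh_f.points, co.Model1Params(), 2)
        drive = tr.precompute_csf_drive(h, 1.2e-10, vdir_f, 0.0)
        tau = np.array([21600.0, 86400.0])
        mins = {}
        for level in (1, 2, 3):
            mesh = h.mesh(level)
            vdir = co.directional_velocity(mesh.points, co.Model1Params(), 2)
            sol = tr.solve_transport(
                mesh, h.dt(level), 1.2e-10, vdir, 0.0, drive, tau, level=level
            )
            mins[level] = -sol.min_value
        assert mins[3] < mins[2] < mins[1]

    def test_second_order_level_convergence_of_functionals(self):
        # deterministic mean-coefficient solves on three nested levels: the
        # Richardson ratio of successive functional differences ~ 2^2
        spec = GeometrySpec(dimension=2, n_levels=3)
        h = build_surrogate_hierarchy(spec, dt_base=450.0, T=43200.0)
        mesh_f = h.mesh(3)
        p2 = co.Model2Params(v_avg=1e-6)
        scale = co.calibrate_model2_scale(mesh_f, p2)
        vbar = p2.gamma_shape * scale
        D = 1.2e-8
        drive = tr.precompute_csf_drive(
            h, D, vbar * co.model2_profile(mesh_f.points, p2), p2.r
        )
        tau = tr.default_tau_grid(24)
        Q = {}
        for level in (1, 2, 3):
            m = h.mesh(level)
            v = vbar * co.model2_profile(m.points, p2)
            sol = tr.solve_transport(m, h.dt(level), D, v, p2.r, drive, tau, level=level)
            Q[level] = (tr.functional_weights(m) @ sol.snapshots.T).ravel()
        order = np.log2(np.abs(Q[2] - Q[1]).max() / np.abs(Q[3] - Q[2]).max())
        assert order == pytest.approx(2.0, abs=0.75)


class TestFunctionals:
    def test_constant_concentration(self, small_hier, mean_drive):
        mesh = small_hier.mesh(1)
        sol = tr.TransportSolution(1, np.array([0.0]), np.ones((1, mesh.n_vertices)), 0.0)
        F = tr.evaluate_functionals(sol, mesh)
        s = mesh.measure_scale
        assert F.values[0, 0] == pytest.approx(s * mesh.region_volume("gray"), rel=1e-12)
        assert F.values[1, 0] == pytest.approx(s * mesh.region_volume("white"), rel=1e-12)
        assert F.values[2, 0] == pytest.approx(1.0, rel=1e-12)
        assert F.values[3, 0] == pytest.approx(1.0, rel=1e-12)

    def test_linearity(self, small_hier):
        mesh = small_hier.mesh(1)
        rng = np.random.default_rng(0)
        a = rng.standard_normal(mesh.n_vertices)
        b = rng.standard_normal(mesh.n_vertices)
        W = tr.functional_weights(mesh)
        assert np.allclose(W @ (a + b), W @ a + W @ b, rtol=1e-12)

    def test_zero_concentration(self, small_hier):
        mesh = small_hier.mesh(1)
        sol = tr.TransportSolution(1, np.array([0.0]), np.zeros((1, mesh.n_vertices)), 0.0)
        assert np.all(tr.evaluate_functionals(sol, mesh).values == 0)


class TestPeclet:
    def test_reference_magnitude(self):
        assert tr.peclet_global() == pytest.approx(0.084 * 1.7e-7 / 1.2e-10)
        assert tr.peclet_global() >= 100

    def test_zero_velocity(self):
        assert tr.peclet_global(v_avg=0.0) == 0

    def test_linear_in_length_scale(self):
        assert tr.peclet_global(L_hat=0.168) == pytest.approx(2 * tr.peclet_global())

    def test_report_includes_per_level_cell_numbers(self, small_hier):
        rep = tr.peclet_report(small_hier)
        assert set(rep["cell"]) == {1, 2}
        assert rep["cell"][2] == pytest.approx(rep["cell"][1] / 2, rel=1e-6)
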