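"""Solver verification: closed-form bars, patch test, constraints, linearity."""

import numpy as np
import pytest

import toothfea as tf
from toothfea.fem import apply_constraints, assemble
from conftest import axial_bar_constraints, face_loads


@pytest.fixture(scope="module")
def solution(bar_mesh, dentine_materials):
    f = face_loads(bar_mesh, 2, 40.0, [0.0, 0.0, 1.0])  # 1 MPa -> 100 N
    cs = axial_bar_constraints(bar_mesh)
    disp = tf.solve(bar_mesh, dentine_materials, f, cs)
    stress = tf.recover_stress(bar_mesh, dentine_materials, disp)
    return f, disp, stress


class TestAxialBar:
    """10x10x40 mm dentine bar under 100 N axial load (roller far end)."""

    def test_load_resultant_is_100N(self, solution):
        f, _, _ = solution
        np.testing.assert_allclose(f.sum(axis=0), [0.0, 0.0, 100.0], atol=1e-10)

    def test_end_displacement_matches_FL_over_EA(self, solution, bar_mesh):
        _, disp, _ = solution
        uz = disp.u[bar_mesh.node_sets["ZMAX"], 2].mean()
        theory = 100.0 * 40.0 / (18600.0 * 100.0)
        assert uz == pytest.approx(theory, rel=0.005)

    def test_axial_stress_is_F_over_A(self, solution):
        _, _, stress = solution
        szz = stress.sigma[:, 2]
        np.testing.assert_allclose(szz, 1.0, rtol=0.01)

    def test_equilibrium_residual(self, solution):
        _, disp, _ = solution
        assert disp.equilibrium_residual < 1e-8

    def test_zero_load_gives_zero_displacement(self, bar_mesh, dentine_materials):
        cs = axial_bar_constraints(bar_mesh)
        disp = tf.solve(bar_mesh, dentine_materials, np.zeros((bar_mesh.n_nodes, 3)), cs)
        assert np.abs(disp.u).max() == 0.0

    def test_doubling_load_doubles_displacement(self, solution, bar_mesh, dentine_materials):
        f, disp, _ = solution
        cs = axial_bar_constraints(bar_mesh)
        disp2 = tf.solve(bar_mesh, dentine_materials, 2.0 * f, cs)
        np.testing.assert_allclose(disp2.u, 2.0 * disp.u, rtol=1e-9, atol=1e-15)


class TestCantilever:
    def test_tip_deflection_matches_beam_theory(self, dentine_materials):
        """4x4x40 slender beam, clamped end, transverse tip load."""
        beam = tf.generate_validation_solid("cantilever", (4.0, 4.0, 40.0), 2.0)
        cs = tf.ConstraintSet.from_node_sets(beam, {"ZMIN": "xyz"})
        P = 10.0
        f = face_loads(beam, 2, 40.0, [P / 16.0, 0.0, 0.0])
        disp = tf.solve(beam, dentine_materials, f, cs)
        ux = disp.u[beam.node_sets["ZMAX"], 0].mean()
        E, L = 18600.0, 40.0
        I = 4.0 * 4.0**3 / 12.0
        assert ux == pytest.approx(P * L**3 / (3.0 * E * I), rel=0.05)


class TestPatchTest:
    def test_linear_displacement_gives_exact_constant_stress(self, dentine_materials):
        """Quadratic elements reproduce linear fields exactly (patch test)."""
        cube = tf.generate_validation_solid("cube", (2.0, 2.0, 2.0), 1.0)
        A = np.array([[1e-3, 4e-4, -2e-4], [3e-4, -5e-4, 1e-4], [-1e-4, 2e-4, 8e-4]])
        u = cube.nodes @ A.T  # u_i = A_ij x_j, a uniform-strain state
        stress = tf.recover_stress(cube, dentine_materials, u)
        eps = 0.5 * (A + A.T)
        D = dentine_materials[tf.Region.DENTINE].elasticity_matrix()
        voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
        expected = D @ voigt
        scale = np.abs(expected).max()
        assert np.abs(stress.sigma - expected).max() < 1e-9 * scale

    def test_hydrostatic_displacement_has_no_deviatoric_stress(self, dentine_materials):
        cube = tf.generate_validation_solid("cube", (2.0, 2.0, 2.0), 1.0)
        u = 1e-3 * cube.nodes  # pure volumetric expansion
        stress = tf.recover_stress(cube, dentine_materials, u)
        mean = stress.sigma[:, :3].mean(axis=1, keepdims=True)
        dev = np.concatenate([stress.sigma[:, :3] - mean, stress.sigma[:, 3:]], axis=1)
        assert np.abs(dev).max() < 1e-9 * np.abs(stress.sigma).max()


class TestConstraints:
    def test_no_constraints_reports_free_rigid_mode(self, bar_mesh, dentine_materials):
        with pytest.raises(tf.ConstraintError, match="insufficient constraints"):
            tf.solve(
                bar_mesh, dentine_materials,
                np.zeros((bar_mesh.n_nodes, 3)), tf.ConstraintSet({}),
            )

    def test_partial_constraints_leave_named_mode_free(self, bar_mesh, dentine_materials):
        # fixing only z on one face leaves in-plane translations free
        zmin = bar_mesh.node_sets["ZMIN"]
        cs = tf.ConstraintSet({int(n): frozenset("z") for n in zmin})
        with pytest.raises(tf.ConstraintError, match="translation"):
            tf.solve(bar_mesh, dentine_materials, np.zeros((bar_mesh.n_nodes, 3)), cs)

    def test_constrained_dofs_are_exactly_zero(self, bar_mesh, dentine_materials):
        cs = tf.ConstraintSet.from_node_sets(bar_mesh, {"ZMIN": "xyz"})
        f = face_loads(bar_mesh, 2, 40.0, [0.3, -0.2, 1.0])
        disp = tf.solve(bar_mesh, dentine_materials, f, cs)
        assert np.abs(disp.u[bar_mesh.node_sets["ZMIN"]]).max() == 0.0

    def test_tooth_constraint_pattern_removes_rigid_modes(self, coarse_tooth):
        mesh, _ = coarse_tooth
        cs = tf.tooth_constraints(mesh)
        from toothfea.fem import check_rigid_modes

        check_rigid_modes(mesh, cs)  # must not raise


class TestSparseDenseOracle:
    def test_sparse_solve_matches_dense_solve_on_small_mesh(self, dentine_materials):
        mesh = tf.generate_validation_solid("bar", (2.0, 2.0, 6.0), 2.0)
        assert 3 * mesh.n_nodes <= 300
        f = face_loads(mesh, 2, 6.0, [0.2, 0.1, 1.0]).reshape(-1)
        cs = tf.ConstraintSet.from_node_sets(mesh, {"ZMIN": "xyz"})
        K = assemble(mesh, dentine_materials)
        K_ff, f_f, free = apply_constraints(K, f, cs)
        u_sparse = tf.solve(mesh, dentine_materials, f, cs).u.reshape(-1)[free]
        u_dense = np.linalg.solve(K_ff.toarray(), f_f)
        np.testing.assert_allclose(u_sparse, u_dense, rtol=1e-9, atol=1e-18)


class TestConvergence:
    def test_cantilever_error_decreases_under_refinement(self, dentine_materials):
        E, L, P = 18600.0, 24.0, 5.0
        I = 4.0 * 4.0**3 / 12.0
        theory = P * L**3 / (3.0 * E * I)
        errors = []
        for h in (4.0, 2.0):
            beam = tf.generate_validation_solid("cantilever", (4.0, 4.0, L), h)
            cs = tf.ConstraintSet.from_node_sets(beam, {"ZMIN": "xyz"})
            f = face_loads(beam, 2, L, [P / 16.0, 0.0, 0.0])
            disp = tf.solve(beam, dentine_materials, f, cs)
            ux = disp.u[beam.node_sets["ZMAX"], 0].mean()
            errors.append(abs(ux - theory))
        assert errors[1] < errors[0]
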