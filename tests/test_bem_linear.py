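"""Surface-charge operator, GMRES solve, and the linear-core oracle."""

import numpy as np
import pytest

import coilcore as cc
from coilcore.bem_linear import (SingleLayerOperator, SolverError,
                                 apply_operator, contrast_from_mu,
                                 single_layer_H, solve_charges)
from coilcore.materials import MU0
from conftest import SPHERE_MU_R, SPHERE_RADIUS, dipole_H


@pytest.fixture(scope="module")
def small_faces():
    """All faces (inner + boundary) of a small cylinder mesh, ~400 faces."""
    mesh = cc.generate_primitive("cylinder", radius=0.01, height=0.03,
                                 n_azimuthal=6, n_radial=1, n_layers=3)
    return cc.build_faces(mesh)


def flat_disc_faces(radius=0.01, n=96, rings=8):
    mesh = cc.generate_primitive("cylinder", radius=radius, height=radius,
                                 n_azimuthal=n, n_radial=rings, n_layers=1)
    fs = cc.build_faces(mesh)
    bottom = fs.subset(fs.is_boundary & (np.abs(fs.center[:, 2]) < 1e-12))
    return bottom


class TestSingleLayerH:
    def test_zero_charge(self, small_faces):
        H = single_layer_H(small_faces, np.zeros(small_faces.n_faces),
                           [[0.05, 0, 0]])
        assert np.allclose(H, 0.0)

    def test_uniform_disc_on_axis_closed_form(self):
        # field of a uniformly charged disc on its axis:
        # H_z = rho/(2 mu0) (1 - z / sqrt(z^2 + R^2))
        R = 0.01
        disc = flat_disc_faces(R)
        rho = np.full(disc.n_faces, 2.5e-3)  # tesla
        for z in (0.002, 0.005, 0.02):
            # the field of positive charge points away from the disc on
            # either side, independent of the face orientation convention;
            # a wide exact-integration radius keeps quadrature error below
            # the 0.5% comparison threshold at the closest point
            H = single_layer_H(disc, rho, [[0, 0, z]], near_factor=30.0)[0]
            expect = rho[0] / (2 * MU0) * (1 - z / np.hypot(z, R))
            assert H[2] == pytest.approx(expect, rel=5e-3)

    def test_monopole_far_field(self, small_faces):
        rho = np.full(small_faces.n_faces, 1e-3)
        # total charge q = sum(rho * area) over the closed boundary +
        # inner faces; use boundary only with uniform rho for a clean q
        b = small_faces.subset(small_faces.is_boundary)
        rho_b = np.full(b.n_faces, 1e-3)
        q = float((rho_b * b.area).sum())
        r = 2.0
        H = single_layer_H(b, rho_b, [[r, 0, 0]])[0]
        assert H[0] == pytest.approx(q / (4 * np.pi * MU0 * r**2), rel=1e-3)

    def test_jump_across_charged_face(self, small_faces):
        # the normal field jumps by exactly rho/mu0 across a charged face
        i = int(np.argmax(small_faces.area))
        rho = np.zeros(small_faces.n_faces)
        rho[i] = 3e-3
        c = small_faces.center[i]
        n = small_faces.normal[i]
        # offset well below the face size so the self-face solid angle is
        # +/- 2 pi to the comparison precision
        eps = 1e-7 * np.sqrt(small_faces.area[i])
        Hp = single_layer_H(small_faces, rho, (c + eps * n)[None])[0]
        Hm = single_layer_H(small_faces, rho, (c - eps * n)[None])[0]
        assert np.dot(Hp - Hm, n) == pytest.approx(rho[i] / MU0, rel=1e-6)
        # and the principal value on the face is the two-sided average
        Hpv = single_layer_H(small_faces, rho, c[None])[0]
        assert np.allclose(Hpv, (Hp + Hm) / 2, atol=1e-9 * abs(Hp).max())


class TestApplyOperator:
    def test_zero_contrast_is_half_identity(self, small_faces):
        rng = np.random.default_rng(0)
        rho = rng.standard_normal(small_faces.n_faces)
        out = apply_operator(small_faces, 0.0, rho)
        assert np.allclose(out, 0.5 * rho, rtol=1e-14)

    def test_single_face_self_term_is_half(self):
        mesh = cc.core_mesh.TetCoreMesh(np.eye(4, 3), [[0, 1, 2, 3]])
        fs = cc.build_faces(mesh).subset([True, False, False, False])
        out = apply_operator(fs, 0.7, np.array([2.0]))
        assert out[0] == pytest.approx(1.0, rel=1e-14)

    def test_matrix_free_equals_dense(self, small_faces):
        rng = np.random.default_rng(1)
        rho = rng.standard_normal(small_faces.n_faces)
        op = SingleLayerOperator(small_faces)
        mf = op.matvec(rho)
        dense = op.assemble_dense() @ rho
        assert np.linalg.norm(mf - dense) <= 1e-10 * np.linalg.norm(dense)

    def test_contrast_bound_enforced(self, small_faces):
        with pytest.raises(ValueError):
            apply_operator(small_faces, 1.5,
                           np.ones(small_faces.n_faces))


class TestSolveCharges:
    def test_zero_rhs(self, small_faces, tmp_path):
        ch, info = solve_charges(small_faces, 0.5,
                                 np.zeros(small_faces.n_faces))
        assert np.all(ch.rho == 0.0)
        assert info["iterations"] <= 1
        ch.to_csv(tmp_path / "rho.csv")
        data = np.loadtxt(tmp_path / "rho.csv", delimiter=",", skiprows=1)
        assert data.shape == (small_faces.n_faces, 8)

    def test_sphere_uniform_field_convergence(self, helmholtz):
        mesh = cc.sphere_mesh(0.025, 10)
        fs = cc.build_faces(mesh).boundary()
        K = contrast_from_mu(3.0)
        bp = cc.primary_B(helmholtz, fs.center)
        rhs = K * np.einsum("ij,ij->i", fs.normal, bp)
        ch, info = solve_charges(fs, K, rhs, tol=1e-8)
        assert info["iterations"] < 30
        assert info["residuals"][-1] <= 1e-8

    def test_gmres_equals_dense_solve(self, small_faces):
        rng = np.random.default_rng(2)
        K = rng.uniform(-0.5, 0.9, small_faces.n_faces)
        rhs = rng.standard_normal(small_faces.n_faces) * 1e-3
        op = SingleLayerOperator(small_faces)
        ch, _ = solve_charges(small_faces, K, rhs, tol=1e-12, operator=op)
        A = np.diag(np.full(small_faces.n_faces, 0.5)) - \
            K[:, None] * op.assemble_dense()
        direct = np.linalg.solve(A, rhs)
        assert np.linalg.norm(ch.rho - direct) <= 1e-6 * np.linalg.norm(direct)

    def test_nonconvergence_reports_history(self, small_faces):
        rng = np.random.default_rng(3)
        rhs = rng.standard_normal(small_faces.n_faces)
        with pytest.raises(SolverError) as exc:
            solve_charges(small_faces, 0.999, rhs, tol=1e-16, max_iter=2)
        assert exc.value.residuals


class TestLinearCoreSphere:
    def test_magnetization_closed_form(self, sphere_solution, applied_H0):
        # uniformly magnetized sphere: |M| = 3 (mu_r - 1)/(mu_r + 2) |H0|
        expect = 3 * (SPHERE_MU_R - 1) / (SPHERE_MU_R + 2) * \
            np.linalg.norm(applied_H0)
        Mmag = np.linalg.norm(sphere_solution.M, axis=1)
        assert np.mean(Mmag) == pytest.approx(expect, rel=0.02)
        # direction along the applied field
        Mdir = sphere_solution.M.mean(axis=0)
        assert Mdir[2] / np.linalg.norm(Mdir) == pytest.approx(1.0, abs=1e-3)

    def test_exterior_dipole_field(self, sphere_solution, applied_H0):
        a = SPHERE_RADIUS
        m = (4 * np.pi * a**3 / 3) * 1.2 * applied_H0
        pts = np.array([[3 * a, 0, 0], [0, 0, 2 * a], [2 * a, 0, 2 * a]])
        Hs = sphere_solution.secondary_H_outside(pts)
        Hd = dipole_H(m, pts)
        err = np.linalg.norm(Hs - Hd, axis=1) / np.linalg.norm(Hd, axis=1)
        assert np.all(err < 0.02)

    def test_vacuum_core_is_transparent(self, helmholtz):
        mesh = cc.sphere_mesh(0.02, 6)
        sol = cc.solve_linear_core(mesh, 1.0, helmholtz)
        assert np.allclose(sol.M, 0.0)
        assert np.allclose(sol.rho, 0.0)

    def test_total_bound_charge_vanishes(self, sphere_solution):
        f = sphere_solution.faces
        net = abs(float((sphere_solution.rho * f.area).sum()))
        scale = float((np.abs(sphere_solution.rho) * f.area).sum())
        assert net <= 1e-6 * scale

    def test_charge_equals_normal_magnetization(self, sphere_solution):
        # rho_s = mu0 n.M; reconstruction from the adjacent-tet field.
        # The flat-facet discretization limits pointwise agreement to a few
        # percent at this resolution (it improves under refinement, checked
        # in test_identity_error_decreases_with_refinement).
        f = sphere_solution.faces
        nM = np.einsum("ij,ij->i", f.normal,
                       sphere_solution.M[f.plus_tet])
        err = np.sqrt(np.mean((sphere_solution.rho / MU0 - nM) ** 2))
        assert err <= 0.035 * np.sqrt(np.mean(nM**2))

    def test_identity_error_decreases_with_refinement(self, helmholtz):
        errs = []
        for n in (8, 14):
            mesh = cc.sphere_mesh(SPHERE_RADIUS, n)
            sol = cc.solve_linear_core(mesh, SPHERE_MU_R, helmholtz)
            f = sol.faces
            nM = np.einsum("ij,ij->i", f.normal, sol.M[f.plus_tet])
            errs.append(np.sqrt(np.mean((sol.rho / MU0 - nM) ** 2))
                        / np.sqrt(np.mean(nM**2)))
        assert errs[1] < errs[0]

    def test_linearity_in_terminal_current(self, helmholtz):
        mesh = cc.sphere_mesh(0.02, 6)
        sol1 = cc.solve_linear_core(mesh, 3.0, helmholtz)
        coil10 = cc.FilamentCoil(helmholtz.start, helmholtz.end,
                                 helmholtz.weight, I0=10 * helmholtz.I0)
        sol10 = cc.solve_linear_core(mesh, 3.0, coil10)
        assert np.allclose(sol10.rho, 10 * sol1.rho, rtol=1e-6)
        assert np.allclose(sol10.M, 10 * sol1.M, rtol=1e-6)

    def test_invalid_permeability(self, helmholtz):
        mesh = cc.sphere_mesh(0.02, 4)
        with pytest.raises(ValueError):
            cc.solve_linear_core(mesh, 0.5, helmholtz)
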