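"""Successive-substitution nonlinear solver: units tests on a small core."""

import numpy as np
import pytest

import coilcore as cc
from coilcore.materials import MU0, AnhystereticCurve
from coilcore.nonlinear import (BemWorkspace, face_contrasts,
                                initialize_state, update_permeability,
                                update_secondary_field)


def constant_mu_curve(mu_r: float) -> AnhystereticCurve:
    """Field-independent curve: Froelich with a vanishing a2."""
    return AnhystereticCurve("froelich", 1.0 / ((mu_r - 1.0) * MU0), 1e-30)


class TestInitializeState:
    def test_zero_current_gives_initial_permeability(self, coarse_cylinder):
        c = coarse_cylinder
        coil0 = cc.FilamentCoil(c["coil"].start, c["coil"].end,
                                c["coil"].weight, I0=0.0)
        ws0 = c["ws"].with_current(0.0)
        curve = cc.preset_material(2)
        st = initialize_state(c["mesh"], c["faces"], curve, coil0,
                              workspace=ws0)
        assert np.allclose(st.mu_r, cc.initial_permeability(curve))
        assert np.all(st.rho == 0) and np.all(st.H_s == 0)

    def test_strong_drive_saturates_everywhere(self, coarse_cylinder):
        c = coarse_cylinder
        ws = c["ws"].with_current(1e9)
        st = initialize_state(c["mesh"], c["faces"], cc.preset_material(3),
                              ws.coil, workspace=ws)
        assert np.all(st.mu_r < 1.01)

    def test_fixture_drive_below_small_signal(self, coarse_cylinder):
        c = coarse_cylinder
        curve = cc.preset_material(2)
        st = initialize_state(c["mesh"], c["faces"], curve, c["coil"],
                              workspace=c["ws"])
        assert np.all(st.mu_r < cc.initial_permeability(curve))


class TestUpdateSecondaryField:
    def test_zero_charge_zero_field(self, coarse_cylinder):
        c = coarse_cylinder
        st = initialize_state(c["mesh"], c["faces"], cc.preset_material(1),
                              c["coil"], workspace=c["ws"])
        hs = update_secondary_field(st, c["faces"], c["ws"])
        assert np.all(hs == 0)

    def test_beta_zero_is_pure_centroid(self, coarse_cylinder):
        c = coarse_cylinder
        rng = np.random.default_rng(0)
        st = initialize_state(c["mesh"], c["faces"], cc.preset_material(1),
                              c["coil"], workspace=c["ws"])
        st.rho = rng.standard_normal(c["faces"].n_faces) * 1e-3
        hs0 = update_secondary_field(st, c["faces"], c["ws"], beta=0.0)
        assert np.allclose(hs0, c["ws"].secondary_at_centroids(st.rho))
        hs_b = update_secondary_field(st, c["faces"], c["ws"], beta=0.3)
        assert not np.allclose(hs0, hs_b)


class TestUpdatePermeability:
    def test_alpha_one_is_raw_curve(self, coarse_cylinder):
        c = coarse_cylinder
        curve = cc.preset_material(2)
        st = initialize_state(c["mesh"], c["faces"], curve, c["coil"],
                              workspace=c["ws"])
        mu = update_permeability(st, curve, alpha=1.0, workspace=c["ws"])
        H = np.linalg.norm(st.H_total, axis=1)
        assert np.allclose(mu, cc.relative_permeability(curve, H))

    def test_uniform_field_is_smoothing_fixed_point(self, coarse_cylinder):
        c = coarse_cylinder
        S = c["ws"].smoother(0.5)
        uniform = np.full(c["mesh"].n_tets, 42.0)
        assert np.allclose(S @ uniform, uniform)

    def test_smoothing_contracts_checkerboard(self, coarse_cylinder):
        c = coarse_cylinder
        rng = np.random.default_rng(1)
        mu = np.where(rng.random(c["mesh"].n_tets) > 0.5, 100.0, 10.0)
        out = c["ws"].smoother(0.5) @ mu
        assert out.max() - out.min() <= mu.max() - mu.min()
        assert out.min() >= mu.min() - 1e-9 and out.max() <= mu.max() + 1e-9
        # checkerboard built on an independent set: every high tet is
        # surrounded by low neighbors, so the spread strictly contracts
        nbrs = c["mesh"].tet_neighbors()
        high = np.zeros(c["mesh"].n_tets, dtype=bool)
        blocked = np.zeros_like(high)
        for t in range(c["mesh"].n_tets):
            if not blocked[t]:
                high[t] = True
                blocked[nbrs[t]] = True
        mu2 = np.where(high, 100.0, 10.0)
        out2 = c["ws"].smoother(0.5) @ mu2
        assert out2.max() - out2.min() < mu2.max() - mu2.min()

    def test_alpha_out_of_range(self, coarse_cylinder):
        c = coarse_cylinder
        st = initialize_state(c["mesh"], c["faces"], cc.preset_material(1),
                              c["coil"], workspace=c["ws"])
        with pytest.raises(ValueError):
            update_permeability(st, cc.preset_material(1), alpha=0.0,
                                workspace=c["ws"])


class TestFaceContrasts:
    def test_uniform_permeability_zero_inner_contrast(self, coarse_cylinder):
        c = coarse_cylinder
        st = initialize_state(c["mesh"], c["faces"], constant_mu_curve(50.0),
                              c["coil"], workspace=c["ws"])
        K = face_contrasts(st, c["faces"])
        inner = ~c["faces"].is_boundary
        assert np.allclose(K[inner], 0.0)
        # boundary faces: K = (mu - mu0)/(mu + mu0)
        assert np.allclose(K[~inner], (50.0 - 1) / (50.0 + 1), rtol=1e-9)

    def test_boundary_contrast_arithmetic(self, coarse_cylinder):
        c = coarse_cylinder
        st = initialize_state(c["mesh"], c["faces"], constant_mu_curve(1000.0),
                              c["coil"], workspace=c["ws"])
        st.mu_r[:] = 1000.0
        K = face_contrasts(st, c["faces"])
        b = c["faces"].is_boundary
        assert np.allclose(K[b], 999.0 / 1001.0)


class TestIterate:
    def test_constant_curve_reduces_to_linear(self, coarse_cylinder):
        # with a field-independent curve the all-faces pipeline must match
        # the boundary-only linear solver: inner faces carry no charge
        c = coarse_cylinder
        mu_r = 5.0
        sol, log = cc.solve_nonlinear_core(c["mesh"], constant_mu_curve(mu_r),
                                           c["coil"], workspace=c["ws"])
        assert len(log.e1) <= 2
        inner = ~c["faces"].is_boundary
        assert np.max(np.abs(sol.rho[inner])) <= 1e-10 * np.max(
            np.abs(sol.rho))
        lin = cc.solve_linear_core(c["mesh"], mu_r, c["coil"])
        rho_b = sol.rho[c["faces"].is_boundary]
        assert np.linalg.norm(rho_b - lin.rho) <= 1e-6 * np.linalg.norm(
            lin.rho)

    def test_two_identical_states_zero_deviations(self):
        from coilcore.nonlinear import ConvergenceLog
        # e1/e2 definition check: identical consecutive vectors -> 0
        rho = np.array([1.0, -2.0, 3.0])
        e1 = np.linalg.norm(rho - rho) / np.linalg.norm(rho)
        assert e1 == 0.0

    def test_weak_field_matches_small_signal_linear(self, coarse_cylinder):
        # at 1 mA the core stays in the flat region of the curve; the
        # nonlinear charges must match the linear solve at mu_r0 within 1%
        c = coarse_cylinder
        curve = cc.preset_material(3)
        ws = c["ws"].with_current(1e-3)
        sol, log = cc.solve_nonlinear_core(c["mesh"], curve, ws.coil,
                                           workspace=ws)
        lin = cc.solve_linear_core(c["mesh"], cc.initial_permeability(curve),
                                   ws.coil)
        rho_b = sol.rho[c["faces"].is_boundary]
        assert np.linalg.norm(rho_b - lin.rho) <= 0.01 * np.linalg.norm(
            lin.rho)

    def test_saturation_sweep_monotone_mu(self, coarse_cylinder):
        c = coarse_cylinder
        curve = cc.preset_material(2)
        means = []
        for I0 in (1e-3, 100.0, 20e3):
            ws = c["ws"].with_current(I0)
            sol, _ = cc.solve_nonlinear_core(c["mesh"], curve, ws.coil,
                                             workspace=ws)
            means.append(float(sol.mu_r.mean()))
        assert means[0] > means[1] > means[2]

    def test_plus_minus_relabeling_invariance(self, coarse_cylinder):
        # permuting tets permutes plus/minus assignments and flips normals;
        # the converged charges must describe the same physical solution
        c = coarse_cylinder
        from coilcore.core_mesh import TetCoreMesh, build_faces
        rng = np.random.default_rng(7)
        perm = rng.permutation(c["mesh"].n_tets)
        mesh2 = TetCoreMesh(c["mesh"].vertices, c["mesh"].tets[perm])
        curve = cc.preset_material(3)
        sol1, _ = cc.solve_nonlinear_core(c["mesh"], curve, c["coil"],
                                          workspace=c["ws"])
        sol2, _ = cc.solve_nonlinear_core(mesh2, curve, c["coil"])
        # compare the secondary field at neutral exterior probe points
        pts = np.array([[0.05, 0.0, -0.02], [0.0, 0.04, 0.01],
                        [-0.03, -0.03, 0.0]])
        H1 = sol1.secondary_H_outside(pts)
        H2 = sol2.secondary_H_outside(pts)
        assert np.allclose(H1, H2, rtol=1e-5)

    def test_divergence_raises_with_advice(self, coarse_cylinder):
        # an unphysically steep curve must fail loudly, not hang
        c = coarse_cylinder
        steep = AnhystereticCurve("froelich", 1e-4, 1e-4)
        with pytest.raises((cc.NonConvergenceError, cc.SolverError)):
            cc.solve_nonlinear_core(c["mesh"], steep, c["coil"],
                                    workspace=c["ws"], max_iter=8,
                                    alpha=1.0)
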