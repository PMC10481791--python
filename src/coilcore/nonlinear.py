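"""Nonlinear magnetostatics by successive substitution over all mesh faces.

The field-dependent core is handled by assuming a constant permeability in
every tetrahedron and impressing magnetic surface charge on *every* face of
the tet mesh — boundary and inner alike — so that the normal flux density
stays continuous across each face.  One fixed-point sweep is:

1. evaluate the secondary field H_s at the tet centroids from the current
   charges (zero on the very first sweep);
2. update each tet's permeability from the B-H curve at ``|H_p + H_s|``,
   optionally smoothing it over face-neighbor tets;
3. form the differential contrast ``K = (mu+ - mu-)/(mu+ + mu-)`` on every
   face (``mu- = mu0`` on the boundary);
4. re-solve the surface-charge equation with these contrasts (GMRES,
   warm-started from the previous charges).

The sweep repeats until the relative deviations of the charge density (e1)
and of the permeability field (e2) both drop below their tolerances.  An
optional stabilizer replaces a fraction ``beta`` of the centroid field with
the average of the four just-inside face-center values reconstructed from
the charge jump; it is off by default and auto-engaged on divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from . import coil as coil_mod
from .bem_linear import (ChargeDensity, SingleLayerOperator, SolverError,
                         solve_charges, tet_field_matrices)
from .core_mesh import FaceSet, TetCoreMesh, build_faces
from .fields import CoilCoreSolution
from .materials import MU0, AnhystereticCurve, relative_permeability


class NonConvergenceError(RuntimeError):
    """The successive-substitution iteration diverged.

    Carries the convergence log; typical remedies are a smaller smoothing
    weight ``alpha`` or a larger face-averaging weight ``beta`` (materials
    with a very high permeability variation rate may not converge at all).
    """

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


@dataclass
class ConvergenceLog:
    """Per-iteration relative deviations and solver effort."""

    e1: list = field(default_factory=list)   # charge-density deviation
    e2: list = field(default_factory=list)   # permeability deviation
    gmres_iterations: list = field(default_factory=list)
    mu_mean: list = field(default_factory=list)


@dataclass
class CoreState:
    """Mutable per-iteration state of the nonlinear solve."""

    mu_r: np.ndarray            # (T,) relative permeability
    H_s: np.ndarray             # (T, 3) secondary field, A/m
    H_p: np.ndarray             # (T, 3) primary field at centroids, A/m
    rho: np.ndarray             # (F,) face charge density, T
    iteration: int = 0

    @property
    def H_total(self) -> np.ndarray:
        return self.H_p + self.H_s


class BemWorkspace:
    """Precomputed geometry-dependent quantities shared across iterations
    (and across materials on the same mesh/coil)."""

    def __init__(self, mesh: TetCoreMesh, faces: FaceSet | None,
                 coil: coil_mod.FilamentCoil, dense: bool | None = None):
        self.mesh = mesh
        self.faces = faces if faces is not None else build_faces(mesh)
        self.coil = coil
        f = self.faces
        self.bp_face = coil_mod.primary_B(coil, f.center)
        self.bp_n = np.einsum("ij,ij->i", f.normal, self.bp_face)
        self.hp_tet = coil_mod.primary_B(coil, mesh.centroids) / MU0
        self.operator = SingleLayerOperator(f)
        if dense is None:
            dense = f.n_faces <= 16000
        if dense:
            self.operator.use_dense()
        self.hs_matrices = tet_field_matrices(f, mesh)
        self.neighbor_smoother = None  # built lazily per alpha
        self._fc_near = None  # lazily built face-center PV machinery

    def with_current(self, I0: float) -> "BemWorkspace":
        """Same geometry at a different terminal current.

        All primary fields are exactly linear in I0, so the precomputed
        matrices are shared and only the field vectors are rescaled.
        """
        ws = object.__new__(BemWorkspace)
        ws.__dict__.update(self.__dict__)
        scale = I0 / self.coil.I0
        ws.coil = coil_mod.FilamentCoil(
            self.coil.start, self.coil.end, self.coil.weight, I0,
            self.coil.n_parallel)
        ws.bp_face = self.bp_face * scale
        ws.bp_n = self.bp_n * scale
        ws.hp_tet = self.hp_tet * scale
        return ws

    def secondary_at_centroids(self, rho: np.ndarray) -> np.ndarray:
        M = self.hs_matrices
        out = np.stack([M[0] @ rho, M[1] @ rho, M[2] @ rho], axis=1)
        return out / (4.0 * np.pi * MU0)

    def pv_at_face_centers(self, rho: np.ndarray, chunk: int = 2 ** 21
                           ) -> np.ndarray:
        """Principal-value H_s at every face center, (F, 3).

        Far faces by the centroid rule, near faces (within 3 face sizes,
        including the face itself) by precomputed exact-integral
        corrections; the corrections are geometry-only and reused across
        sweeps.
        """
        from scipy.spatial import cKDTree

        from ._triangle import centroid_grad, grad_integral

        f = self.faces
        F = f.n_faces
        if self._fc_near is None:
            size = np.sqrt(f.area)
            tree = cKDTree(f.center)
            # observation centers within 3 source-face sizes, per source
            groups = tree.query_ball_point(f.center, r=3.0 * size,
                                           workers=-1)
            j = np.repeat(np.arange(F), [len(g) for g in groups])
            i = np.fromiter((x for g in groups for x in g), dtype=np.int64,
                            count=j.size)
            corr = np.empty((j.size, 3))
            for b0 in range(0, j.size, 262144):
                b1 = min(b0 + 262144, j.size)
                jb, ib = j[b0:b1], i[b0:b1]
                exact = grad_integral(f.tri[jb], f.center[ib])
                approx = centroid_grad(f.area[jb], f.center[jb],
                                       f.center[ib])
                approx[ib == jb] = 0.0  # the far sum skips the diagonal
                corr[b0:b1] = exact - approx
            self._fc_near = [sparse.csr_matrix((corr[:, c], (i, j)),
                                               shape=(F, F))
                             for c in range(3)]
        out = np.empty((F, 3))
        q = f.area * rho
        rows = max(1, chunk // F)
        for i0 in range(0, F, rows):
            i1 = min(i0 + rows, F)
            d = f.center[i0:i1, None, :] - f.center[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(r2[:, i0:i1], np.inf)
            w = q / (r2 * np.sqrt(r2))
            out[i0:i1] = np.einsum("ij,ijk->ik", w, d)
        for c in range(3):
            out[:, c] += self._fc_near[c] @ rho
        return out / (4.0 * np.pi * MU0)

    def smoother(self, alpha: float) -> sparse.csr_matrix:
        """Sparse operator for the neighbor-averaged permeability update.

        ``mu <- alpha*mu + (1-alpha)/4 * sum(neighbors)``, with the weight
        of missing neighbors (boundary tets) retained by the tet itself.
        """
        if self.neighbor_smoother is None or self.neighbor_smoother[0] != alpha:
            f = self.faces
            inner = ~f.is_boundary
            i = np.concatenate([f.plus_tet[inner], f.minus_tet[inner]])
            j = np.concatenate([f.minus_tet[inner], f.plus_tet[inner]])
            T = self.mesh.n_tets
            adj = sparse.csr_matrix((np.ones(i.size), (i, j)), shape=(T, T))
            deg = np.asarray(adj.sum(axis=1)).ravel()
            diag = alpha + (1.0 - alpha) * (4.0 - deg) / 4.0
            S = sparse.diags(diag) + (1.0 - alpha) / 4.0 * adj
            self.neighbor_smoother = (alpha, S.tocsr())
        return self.neighbor_smoother[1]


def initialize_state(mesh: TetCoreMesh, faces: FaceSet,
                     curve: AnhystereticCurve, coil,
                     workspace: BemWorkspace | None = None) -> CoreState:
    """First-sweep state: mu from the free-space coil field, zero charges."""
    ws = workspace or BemWorkspace(mesh, faces, coil, dense=False)
    hp = ws.hp_tet
    mu = relative_permeability(curve, np.linalg.norm(hp, axis=1))
    return CoreState(mu_r=mu, H_s=np.zeros_like(hp), H_p=hp,
                     rho=np.zeros(ws.faces.n_faces))


def update_secondary_field(state: CoreState, faces: FaceSet,
                           workspace: BemWorkspace, beta: float = 0.0
                           ) -> np.ndarray:
    """Per-tet H_s from the current charges.

    ``beta = 0`` is the pure centroid evaluation; ``beta > 0`` blends in
    the average of the four just-inside face-center values obtained from
    the principal value and the charge jump rho/(2 mu0) across each face.
    """
    hs = workspace.secondary_at_centroids(state.rho)
    if beta > 0.0:
        f = workspace.faces
        pv = workspace.pv_at_face_centers(state.rho)
        jump = (state.rho / (2.0 * MU0))[:, None] * f.normal
        tf = getattr(f, "tet_faces", None)
        if tf is None:
            raise ValueError("face set lacks tet_faces; build it with "
                             "build_faces on the full mesh")
        # just-inside value for the plus tet is pv - jump, for minus pv + jump
        inside_plus = pv - jump
        inside_minus = pv + jump
        avg = np.zeros_like(hs)
        for k in range(4):
            fk = tf[:, k]
            is_plus = (f.plus_tet[fk] == np.arange(tf.shape[0]))
            avg += np.where(is_plus[:, None], inside_plus[fk], inside_minus[fk])
        avg /= 4.0
        hs = (1.0 - beta) * hs + beta * avg
    state.H_s = hs
    return hs


def update_permeability(state: CoreState, curve: AnhystereticCurve,
                        alpha: float = 1.0,
                        workspace: BemWorkspace | None = None) -> np.ndarray:
    """Raw B-H update followed by neighbor smoothing with weight alpha."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("smoothing weight alpha must be in (0, 1]")
    mu = relative_permeability(curve, np.linalg.norm(state.H_total, axis=1))
    if alpha < 1.0:
        if workspace is None:
            raise ValueError("neighbor smoothing needs a workspace")
        mu = workspace.smoother(alpha) @ mu
    state.mu_r = mu
    return mu


def face_contrasts(state: CoreState, faces: FaceSet) -> np.ndarray:
    """Differential contrast K = (mu+ - mu-)/(mu+ + mu-) on every face.

    On boundary faces the minus side is vacuum (mu- = mu0).
    """
    mu_p = state.mu_r[faces.plus_tet]
    mu_m = np.where(faces.is_boundary, 1.0, state.mu_r[faces.minus_tet])
    return (mu_p - mu_m) / (mu_p + mu_m)


def iterate(state: CoreState, faces: FaceSet, curve: AnhystereticCurve,
            coil, alpha: float = 0.4, beta: float = 0.0,
            tol_e1: float = 1e-3, tol_e2: float = 5e-3, max_iter: int = 30,
            gmres_tol: float = 1e-8, mesh: TetCoreMesh | None = None,
            workspace: BemWorkspace | None = None,
            auto_stabilize: bool = True, verbose: bool = False):
    """Run successive substitution to convergence.

    Returns ``(CoilCoreSolution, ConvergenceLog)``.  Divergence (e1 or e2
    increasing for 5 consecutive sweeps) raises
    :class:`NonConvergenceError`; with ``auto_stabilize`` one retry is made
    with the face-averaging stabilizer engaged (beta = 0.25).
    """
    if workspace is None:
        if mesh is None:
            raise ValueError("iterate needs a workspace or the tet mesh")
        workspace = BemWorkspace(mesh, faces, coil)
    return _iterate(state, curve, alpha, beta, tol_e1, tol_e2, max_iter,
                    gmres_tol, workspace, auto_stabilize, verbose)


def _iterate(state, curve, alpha, beta, tol_e1, tol_e2, max_iter, gmres_tol,
             ws: BemWorkspace, auto_stabilize, verbose):
    log = ConvergenceLog()
    f = ws.faces
    rho_prev = state.rho.copy()
    mu_prev = state.mu_r.copy()
    rising = 0
    for it in range(1, max_iter + 1):
        update_secondary_field(state, f, ws, beta=beta)
        update_permeability(state, curve, alpha=alpha, workspace=ws)
        K = face_contrasts(state, f)
        rhs = K * ws.bp_n
        try:
            charge, info = solve_charges(f, K, rhs, tol=gmres_tol,
                                         operator=ws.operator,
                                         x0=state.rho if it > 1 else None)
        except SolverError as err:
            raise NonConvergenceError(
                f"charge solve failed at sweep {it}: {err}", log=log) from err
        state.rho = charge.rho
        state.iteration = it

        nr = np.linalg.norm(state.rho)
        e1 = np.linalg.norm(state.rho - rho_prev) / nr if nr > 0 else 0.0
        e2 = (np.linalg.norm(state.mu_r - mu_prev)
              / np.linalg.norm(state.mu_r))
        log.e1.append(e1)
        log.e2.append(e2)
        log.gmres_iterations.append(info["iterations"])
        log.mu_mean.append(float(state.mu_r.mean()))
        if verbose:
            print(f"  sweep {it:2d}: e1={e1:.3e} e2={e2:.3e} "
                  f"gmres={info['iterations']:3d} "
                  f"mu_mean={state.mu_r.mean():.1f}")
        if it > 1 and e1 <= tol_e1 and e2 <= tol_e2:
            break
        if it > 2 and e1 > log.e1[-2] and e2 > log.e2[-2]:
            rising += 1
        else:
            rising = 0
        if rising >= 5:
            if auto_stabilize and beta == 0.0:
                fresh = initialize_state(ws.mesh, f, curve, ws.coil,
                                         workspace=ws)
                state.__dict__.update(fresh.__dict__)
                return _iterate(state, curve, alpha, 0.25, tol_e1, tol_e2,
                                max_iter, gmres_tol, ws, False, verbose)
            raise NonConvergenceError(
                "successive substitution diverged (e1/e2 rising for 5 "
                "sweeps); try smaller alpha or larger beta", log=log)
        rho_prev = state.rho.copy()
        mu_prev = state.mu_r.copy()
    else:
        raise NonConvergenceError(
            f"not converged after {max_iter} sweeps "
            f"(e1={log.e1[-1]:.2e}, e2={log.e2[-1]:.2e})", log=log)

    # final outputs use the raw constitutive law at the converged field:
    # the neighbor smoothing is an iteration aid and must not let the
    # reported magnetization exceed the curve's saturation ceiling
    mu_out = relative_permeability(curve,
                                   np.linalg.norm(state.H_total, axis=1))
    M = (mu_out - 1.0)[:, None] * state.H_total
    sol = CoilCoreSolution(coil=ws.coil, mesh=ws.mesh, faces=f,
                           rho=state.rho, I0=ws.coil.I0, mu_r=mu_out,
                           H_total=state.H_total, M=M, curve=curve,
                           convergence=log)
    return sol, log


def solve_nonlinear_core(mesh: TetCoreMesh, curve: AnhystereticCurve, coil,
                         alpha: float = 0.4, beta: float = 0.0,
                         tol_e1: float = 1e-3, tol_e2: float = 5e-3,
                         max_iter: int = 30, workspace: BemWorkspace | None = None,
                         auto_stabilize: bool = True, verbose: bool = False):
    """Convenience wrapper: initialize and iterate on all faces of ``mesh``."""
    ws = workspace or BemWorkspace(mesh, None, coil)
    state = initialize_state(mesh, ws.faces, curve, coil, workspace=ws)
    return _iterate(state, curve, alpha, beta, tol_e1, tol_e2, max_iter,
                    1e-8, ws, auto_stabilize, verbose)
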