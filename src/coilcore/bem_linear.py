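"""Surface-magnetic-charge integral equation and the linear-core solve.

A magnetized body can be replaced, for the purpose of evaluating its
secondary field, by a fictitious surface charge density ``rho`` (units T =
Wb/m^2) on the permeability interfaces:

    H_s(r) = 1/(4 pi mu0) * sum_faces int_f rho (r - r')/|r - r'|^3 dS'.

Enforcing continuity of the normal flux density across each face yields a
Fredholm equation of the second kind for ``rho``:

    rho/2 - K n . (1/4pi) int (r - r')/|r-r'|^3 rho dS' = K n . B_p,

with the permeability contrast ``K = (mu+ - mu-)/(mu+ + mu-)`` and the
self-face integral taken as a principal value (it contributes only the
rho/2 term).  The equation is solved matrix-free with GMRES; interactions
between a face and its vertex-sharing neighbors (including itself) use the
closed-form triangle integrals, everything farther a one-point centroid
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, gmres

from . import coil as coil_mod
from ._triangle import centroid_grad, grad_integral
from .core_mesh import FaceSet, TetCoreMesh, build_faces
from .materials import MU0

FOUR_PI = 4.0 * np.pi


@dataclass
class ChargeDensity:
    """Per-face surface magnetic charge density, tesla (Wb/m^2)."""

    rho: np.ndarray
    faces: FaceSet | None = None

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float).ravel()
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("charge density contains non-finite values")

    def to_csv(self, path) -> None:
        """Face centers, normals, areas and charge densities as CSV."""
        if self.faces is None:
            raise ValueError("no face geometry attached")
        f = self.faces
        np.savetxt(path, np.column_stack([f.center, f.normal, f.area,
                                          self.rho]),
                   delimiter=",",
                   header="cx,cy,cz,nx,ny,nz,area,rho", comments="")


def _as_rho(rho) -> np.ndarray:
    return rho.rho if isinstance(rho, ChargeDensity) else np.asarray(rho, float)


class SolverError(RuntimeError):
    """GMRES failed to reach the requested residual; carries the history."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


def _vertex_face_incidence(faces: FaceSet):
    """vertex id -> list of face indices (CSR-style arrays)."""
    f = faces.faces
    vid = f.ravel()
    fid = np.repeat(np.arange(faces.n_faces), 3)
    order = np.argsort(vid, kind="stable")
    return vid[order], fid[order]


def _neighbor_pairs(faces: FaceSet):
    """(i, j) pairs of faces sharing at least one vertex (includes i = j)."""
    vid, fid = _vertex_face_incidence(faces)
    bounds = np.searchsorted(vid, np.arange(vid.max() + 2))
    pairs = set()
    for v in np.unique(vid):
        group = fid[bounds[v]:bounds[v + 1]]
        for i in group:
            for j in group:
                pairs.add((int(i), int(j)))
    pairs.update((i, i) for i in range(faces.n_faces))
    arr = np.array(sorted(pairs), dtype=np.int64)
    return arr[:, 0], arr[:, 1]


class SingleLayerOperator:
    """Discretized single-layer normal-field operator on a face set.

    Provides the matrix-vector product ``rho -> (1/4pi) sum_j n_i . G_j(c_i)
    rho_j`` both matrix-free (blocked far-field summation plus a sparse
    near-field correction) and as an explicitly assembled dense matrix.
    """

    def __init__(self, faces: FaceSet, chunk: int = 2 ** 23):
        self.faces = faces
        self.chunk = chunk
        self._near = self._build_near_correction()
        self._dense = None

    def _build_near_correction(self) -> sparse.csr_matrix:
        f = self.faces
        rows, cols = _neighbor_pairs(f)
        obs = f.center[rows]
        exact = grad_integral(f.tri[cols], obs)
        approx = centroid_grad(f.area[cols], f.center[cols], obs)
        vals = np.einsum("ij,ij->i", f.normal[rows], exact - approx) / FOUR_PI
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(f.n_faces, f.n_faces))

    def _far_matvec(self, rho: np.ndarray) -> np.ndarray:
        f = self.faces
        n = f.n_faces
        out = np.empty(n)
        q = f.area * rho
        rows = max(1, self.chunk // max(n, 1))
        for i0 in range(0, n, rows):
            i1 = min(i0 + rows, n)
            d = f.center[i0:i1, None, :] - f.center[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(r2[:, i0:i1], np.inf)  # self term is in _near
            w = np.einsum("ik,ijk->ij", f.normal[i0:i1], d) / (r2 * np.sqrt(r2))
            out[i0:i1] = w @ q
        return out / FOUR_PI

    def matvec(self, rho) -> np.ndarray:
        """Matrix-free normal-field product (far centroid + near exact)."""
        rho = _as_rho(rho)
        if self._dense is not None:
            return self._dense @ rho
        return self._far_matvec(rho) + self._near @ rho

    def assemble_dense(self) -> np.ndarray:
        """Explicit (F, F) matrix of the normal-field operator."""
        f = self.faces
        n = f.n_faces
        D = np.empty((n, n))
        rows = max(1, self.chunk // max(n, 1))
        for i0 in range(0, n, rows):
            i1 = min(i0 + rows, n)
            d = f.center[i0:i1, None, :] - f.center[None, :, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(r2[:, i0:i1], np.inf)
            D[i0:i1] = (np.einsum("ik,ijk->ij", f.normal[i0:i1], d)
                        / (r2 * np.sqrt(r2))) * f.area[None, :]
        D /= FOUR_PI
        D += self._near.toarray()
        return D

    def use_dense(self) -> None:
        """Assemble and cache the dense matrix for fast repeated solves."""
        if self._dense is None:
            self._dense = self.assemble_dense()


def apply_operator(faces: FaceSet, K, rho, operator: SingleLayerOperator | None = None
                   ) -> np.ndarray:
    """Left-hand side of the charge equation: rho/2 - K * (n . H-kernel) rho."""
    rho = _as_rho(rho)
    K = np.broadcast_to(np.asarray(K, float), rho.shape)
    if rho.shape[0] != faces.n_faces:
        raise ValueError("charge vector does not match the face set")
    if np.any(np.abs(K) > 1.0 + 1e-12):
        raise ValueError("permeability contrast must satisfy |K| <= 1")
    op = operator if operator is not None else SingleLayerOperator(faces)
    return 0.5 * rho - K * op.matvec(rho)


def solve_charges(faces: FaceSet, K, rhs, tol: float = 1e-8,
                  max_iter: int = 300, operator: SingleLayerOperator | None = None,
                  x0=None):
    """GMRES solution of the surface-charge equation.

    Parameters
    ----------
    K:
        Per-face (or scalar) permeability contrast in [-1, 1].
    rhs:
        Per-face values ``K * n . B_p`` at the face centers, tesla.

    Returns
    -------
    (ChargeDensity, info dict) with the residual history and iteration count.
    """
    rhs = np.asarray(rhs, dtype=float)
    if not np.all(np.isfinite(rhs)):
        raise ValueError("rhs contains non-finite values")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = faces.n_faces
    K = np.broadcast_to(np.asarray(K, float), (n,))
    op = operator if operator is not None else SingleLayerOperator(faces)
    if not rhs.any():
        return (ChargeDensity(np.zeros(n), faces),
                {"iterations": 0, "residuals": []})

    A = LinearOperator((n, n), matvec=lambda x: 0.5 * x - K * op.matvec(x))
    residuals: list[float] = []
    x, info = gmres(A, rhs, rtol=tol, atol=0.0,
                    restart=min(max_iter, 200), maxiter=max_iter, x0=x0,
                    callback=residuals.append, callback_type="pr_norm")
    if info != 0:
        raise SolverError(
            f"GMRES did not converge to rtol={tol} within {max_iter} "
            f"iterations (last residual {residuals[-1] if residuals else None})",
            residuals=residuals)
    return (ChargeDensity(x, faces),
            {"iterations": len(residuals), "residuals": residuals})


# ---------------------------------------------------------------------------
# Secondary-field evaluation from charges


def single_layer_H(faces: FaceSet, rho, points, near_factor: float = 3.0,
                   chunk: int = 2 ** 23) -> np.ndarray:
    """Secondary field H_s (A/m) of the face charges at arbitrary points.

    Far faces use the centroid rule; faces closer to a point than
    ``near_factor`` times their own size are evaluated with the closed-form
    triangle integral (principal value exactly on a face).
    """
    rho = _as_rho(rho)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if rho.shape[0] != faces.n_faces:
        raise ValueError("charge vector does not match the face set")
    out = np.zeros((pts.shape[0], 3))
    q = faces.area * rho
    n = faces.n_faces
    rows = max(1, chunk // max(n, 1))
    size = np.sqrt(faces.area)
    near_r2 = (near_factor * size) ** 2
    for i0 in range(0, pts.shape[0], rows):
        i1 = min(i0 + rows, pts.shape[0])
        p = pts[i0:i1]
        d = p[:, None, :] - faces.center[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        near = r2 < near_r2[None, :]
        inv_r3 = np.where(near, np.inf, r2) ** -1.5
        out[i0:i1] = np.einsum("ij,ijk->ik", q * inv_r3, d)
        if near.any():
            ip, jf = np.nonzero(near)
            exact = grad_integral(faces.tri[jf], p[ip])
            contrib = rho[jf, None] * exact
            np.add.at(out, i0 + ip, contrib)
    return out / (FOUR_PI * MU0)


def tet_field_matrices(faces: FaceSet, mesh: TetCoreMesh, chunk: int = 2 ** 22):
    """(3, T, F) influence matrices: centroid H_s = (1/4pi mu0) Mx,y,z @ rho.

    Faces sharing a vertex with the observation tetrahedron get the exact
    panel integral, the rest the centroid rule.  Stored in float32: the
    entry precision (~1e-7 relative) is far below the panel-quadrature
    discretization error.
    """
    cents = mesh.centroids
    T, F = mesh.n_tets, faces.n_faces
    M = np.empty((3, T, F), dtype=np.float32)
    rows = max(1, chunk // max(F, 1))
    for i0 in range(0, T, rows):
        i1 = min(i0 + rows, T)
        d = cents[i0:i1, None, :] - faces.center[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        w = faces.area[None, :] * r2 ** -1.5
        for c in range(3):
            M[c, i0:i1] = w * d[:, :, c]
    # overwrite vertex-sharing (tet, face) pairs with the exact integral
    vid, fid = _vertex_face_incidence(faces)
    bounds = np.searchsorted(vid, np.arange(mesh.vertices.shape[0] + 1))
    pairs = set()
    for t in range(T):
        for v in mesh.tets[t]:
            for j in fid[bounds[v]:bounds[v + 1]]:
                pairs.add((t, int(j)))
    pairs = np.array(sorted(pairs), dtype=np.int64)
    ti, fj = pairs[:, 0], pairs[:, 1]
    exact = grad_integral(faces.tri[fj], cents[ti])
    for c in range(3):
        M[c][ti, fj] = exact[:, c]
    return M


def contrast_from_mu(mu_r: float) -> float:
    """Permeability contrast K = (mu - mu0)/(mu + mu0) for a linear core."""
    return (mu_r - 1.0) / (mu_r + 1.0)


def solve_linear_core(mesh, mu_r: float, coil, faces: FaceSet | None = None,
                      tol: float = 1e-8, max_iter: int = 300,
                      operator: SingleLayerOperator | None = None):
    """Complete linear-core pipeline.

    (a) solve the charge equation on the boundary faces with the uniform
    contrast ``K = (mu - mu0)/(mu + mu0)``; (b) evaluate the secondary field
    and the magnetization ``M = (mu_r - 1) (H_p + H_s)`` at the tet
    centroids; (c)/(d) expose the secondary/total vector potential through
    the returned solution object.

    ``mesh`` may be a :class:`TetCoreMesh` or ``None`` if a boundary-only
    ``faces`` set is given (exterior quantities only in that case).
    """
    from .fields import CoilCoreSolution

    if mu_r < 1.0:
        raise ValueError("relative permeability must be >= 1")
    if faces is None:
        if mesh is None:
            raise ValueError("need a mesh or a boundary face set")
        faces = build_faces(mesh).boundary()
    K = contrast_from_mu(mu_r)
    bp = coil_mod.primary_B(coil, faces.center)
    rhs = K * np.einsum("ij,ij->i", faces.normal, bp)
    charge, info = solve_charges(faces, K, rhs, tol=tol, max_iter=max_iter,
                                 operator=operator)
    mu_t = H_tot = M = None
    if mesh is not None:
        cents = mesh.centroids
        hp = coil_mod.primary_B(coil, cents) / MU0
        hs = single_layer_H(faces, charge, cents)
        H_tot = hp + hs
        if mu_r > 1e3:
            # High-contrast interior correction: straight evaluation of
            # H_p + H_s inside a strongly permeable core suffers severe
            # cancellation (the interior field is ~mu0/mu of the applied
            # one).  Rebuild the normal field component at boundary tets
            # from the flux jump condition n.H_in = (mu0/mu) n.H_out.
            import logging
            logging.getLogger(__name__).info(
                "applying high-contrast interior correction (mu_r = %g)", mu_r)
            hpv = single_layer_H(faces, charge, faces.center)
            hout = (coil_mod.primary_B(coil, faces.center) / MU0 + hpv
                    + (charge.rho / (2 * MU0))[:, None] * faces.normal)
            n_hin = np.einsum("ij,ij->i", faces.normal, hout) / mu_r
            # distribute per boundary face onto its interior (plus) tet
            corr = np.zeros((mesh.n_tets, 3))
            cnt = np.zeros(mesh.n_tets)
            np.add.at(corr, faces.plus_tet,
                      (n_hin - np.einsum("ij,ij->i", faces.normal,
                                         H_tot[faces.plus_tet]))[:, None]
                      * faces.normal)
            np.add.at(cnt, faces.plus_tet, 1.0)
            touched = cnt > 0
            H_tot[touched] += corr[touched] / cnt[touched, None]
        M = (mu_r - 1.0) * H_tot
        mu_t = np.full(mesh.n_tets, float(mu_r))
    return CoilCoreSolution(coil=coil, mesh=mesh, faces=faces,
                            rho=charge.rho, mu_r=mu_t, H_total=H_tot, M=M,
                            I0=coil.I0, solve_info=info)
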