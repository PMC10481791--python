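"""Post-solve physics: magnetization, inductance, vector potential, E field.

The converged coil + core state is summarized by a
:class:`CoilCoreSolution`: the per-tetrahedron magnetization ``M``, the
face charges ``rho``, and evaluators for every derived quantity.  Because
the magnetization and charges are stored, the assembly can be rigidly moved
or rotated and re-probed without re-solving, and the current rate ``dI/dt``
enters only linearly at evaluation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import coil as coil_mod
from .core_mesh import FaceSet, TetCoreMesh
from .materials import MU0

_FOUR_PI = 4.0 * np.pi

# local tet refinement: 4 corner children + 4 from the central octahedron
_EDGE = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_CHILDREN = [
    (0, 4, 5, 6), (1, 4, 7, 8), (2, 5, 7, 9), (3, 6, 8, 9),
    (4, 5, 6, 8), (4, 5, 7, 8), (5, 7, 8, 9), (5, 6, 8, 9),
]


def _subdivided_moments(p: np.ndarray, moments: np.ndarray):
    """One-level 8-child split of tets (n,4,3); returns child centroids and
    per-child dipole moments (n, 8, 3)."""
    mids = 0.5 * (p[:, [e[0] for e in _EDGE]] + p[:, [e[1] for e in _EDGE]])
    nodes = np.concatenate([p, mids], axis=1)  # (n, 10, 3)
    cents = np.stack([nodes[:, c, :].mean(axis=1) for c in _CHILDREN], axis=1)
    vols = np.stack([
        np.abs(np.linalg.det(nodes[:, c[1:], :] - nodes[:, c[:1], :]) / 6.0)
        for c in _CHILDREN], axis=1)
    frac = vols / vols.sum(axis=1, keepdims=True)
    return cents, moments[:, None, :] * frac[:, :, None]


@dataclass
class CoilCoreSolution:
    """Converged coil + magnetic-core solution.

    Attributes
    ----------
    coil:
        The filament coil driving the problem (terminal current ``I0``).
    mesh, faces:
        Core tet mesh and the face set carrying ``rho`` (boundary-only for
        a linear solve, all faces for a nonlinear one).
    rho:
        Face magnetic charge densities, tesla.
    mu_r, H_total, M:
        Per-tet relative permeability, total field (A/m) and magnetization
        (A/m); ``None`` when the solve was surface-only.
    """

    coil: coil_mod.FilamentCoil
    faces: FaceSet
    rho: np.ndarray
    I0: float
    mesh: TetCoreMesh | None = None
    mu_r: np.ndarray | None = None
    H_total: np.ndarray | None = None
    M: np.ndarray | None = None
    curve: object = None
    solve_info: dict = field(default_factory=dict)
    convergence: object = None
    _L_p: float | None = None

    # -- outputs ----------------------------------------------------------

    @property
    def L_p(self) -> float:
        """Primary (no-core) Neumann self-inductance, henry."""
        if self._L_p is None:
            self._L_p = coil_mod.self_inductance(self.coil)
        return self._L_p

    def core_energy_and_inductance(self, method: str = "auto") -> dict:
        """Core energy U_s = 1/2 int M . B_p dV and inductances, SI units.

        ``L_s = 2 U_s / I0**2`` is the core inductance correction and
        ``L_total = L_p + L_s``.

        ``method``: ``"volume"`` evaluates the magnetization integral
        directly; ``"charge"`` evaluates the identical quantity from the
        face charges and the coil scalar potential, which stays
        well-conditioned at high permeability where the interior field is
        a difference of nearly equal terms; ``"auto"`` picks ``"charge"``
        when the permeability exceeds ~50 (requires a core that does not
        enclose any coil conductor).
        """
        if self.I0 == 0:
            raise ValueError("inductance correction undefined at I0 = 0")
        if method == "auto":
            high = self.mu_r is not None and np.max(self.mu_r) > 50.0
            method = "charge" if high else "volume"
        if method == "charge":
            return charge_energy_and_inductance(self)
        if self.M is None:
            raise ValueError("no volumetric magnetization in this solution")
        bp = coil_mod.primary_B(self.coil, self.mesh.centroids)
        U_s = 0.5 * float(np.einsum("t,tj,tj->", self.mesh.volumes, self.M, bp))
        L_s = 2.0 * U_s / self.I0**2
        return {"U_s": U_s, "L_s": L_s, "L_p": self.L_p,
                "L_total": self.L_p + L_s}

    def secondary_vector_potential(self, points, near_factor: float = 2.0
                                   ) -> np.ndarray:
        """A_s of the magnetized core (V*s/m), centroid dipole rule.

        Tets closer to a point than ``near_factor`` times their own size
        are refined once into 8 children before summation.
        """
        if self.M is None:
            raise ValueError("no volumetric magnetization in this solution")
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cents = self.mesh.centroids
        vols = self.mesh.volumes
        mom = self.M * vols[:, None]
        size = np.cbrt(vols)
        d = pts[:, None, :] - cents[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        near = r2 < (near_factor * size[None, :]) ** 2
        inv_r3 = r2 ** -1.5
        inv_r3[near] = 0.0
        A = np.cross(mom[None, :, :], d)
        A = np.einsum("ij,ijk->ik", inv_r3, A)
        if near.any():
            ip, jt = np.nonzero(near)
            jts = np.unique(jt)
            cc, mm = _subdivided_moments(
                self.mesh.vertices[self.mesh.tets[jts]], mom[jts])
            remap = {int(t): k for k, t in enumerate(jts)}
            for i, j in zip(ip, jt):
                dd = pts[i] - cc[remap[int(j)]]
                rr = np.linalg.norm(dd, axis=1)
                if np.any(rr < 1e-12):
                    raise ValueError(
                        f"A_s evaluation point {pts[i]} coincides with a "
                        "tetrahedron centroid")
                A[i] += (np.cross(mm[remap[int(j)]], dd)
                         / rr[:, None] ** 3).sum(axis=0)
        return MU0 / _FOUR_PI * A

    def total_vector_potential(self, points) -> np.ndarray:
        """A_p + A_s at the given points, V*s/m."""
        A = coil_mod.primary_A(self.coil, points)
        if self.M is not None:
            A = A + self.secondary_vector_potential(points)
        return A

    def total_E(self, points, dIdt: float) -> np.ndarray:
        """Combined induced electric field E = -(dI/dt)(A_p + A_s)/I0, V/m."""
        return (-dIdt / self.I0) * self.total_vector_potential(points)

    def secondary_H_outside(self, points) -> np.ndarray:
        """Secondary field H_s from the stored face charges, A/m."""
        from .bem_linear import single_layer_H
        return single_layer_H(self.faces, self.rho, points)

    # -- rigid motion ------------------------------------------------------

    def transformed(self, rotation=None, translation=None) -> "CoilCoreSolution":
        """Rigidly move/rotate the solved coil + core assembly.

        The magnetization and charges transform covariantly; nothing is
        re-solved.
        """
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return CoilCoreSolution(
            coil=self.coil.transformed(R, t),
            faces=self.faces.transformed(R, t),
            rho=self.rho.copy(),
            I0=self.I0,
            mesh=None if self.mesh is None else self.mesh.transformed(R, t),
            mu_r=None if self.mu_r is None else self.mu_r.copy(),
            H_total=None if self.H_total is None else self.H_total @ R.T,
            M=None if self.M is None else self.M @ R.T,
            curve=self.curve,
            solve_info=self.solve_info,
            convergence=self.convergence,
            _L_p=self._L_p,
        )


def magnetization(state) -> np.ndarray:
    """Per-tet magnetization M = (mu_r - 1) H_total, A/m.

    Accepts anything exposing ``mu_r`` and ``H_total`` arrays (a nonlinear
    :class:`~coilcore.nonlinear.CoreState` or a solution).
    """
    mu = np.asarray(state.mu_r, dtype=float)
    return (mu - 1.0)[:, None] * np.asarray(state.H_total, dtype=float)


def core_energy_and_inductance(solution: CoilCoreSolution) -> dict:
    return solution.core_energy_and_inductance()


def secondary_vector_potential(solution: CoilCoreSolution, points) -> np.ndarray:
    return solution.secondary_vector_potential(points)


def total_E(solution: CoilCoreSolution, points, dIdt: float) -> np.ndarray:
    return solution.total_E(points, dIdt)


def secondary_H_outside(solution: CoilCoreSolution, points) -> np.ndarray:
    return solution.secondary_H_outside(points)


def flux_linkage_inductance(solution: CoilCoreSolution) -> float:
    """Independent core-inductance route: line integral of A_s along the
    coil filaments divided by I0 (flux linkage), henry."""
    A = solution.secondary_vector_potential(solution.coil.midpoints)
    mom = solution.coil.weight[:, None] * solution.coil.segments
    return float(np.einsum("ij,ij->", mom, A)) / solution.I0


def coil_scalar_potential(coil, points, origin, n_quad: int = 24
                          ) -> np.ndarray:
    """Magnetic scalar potential of the coil field (amperes).

    ``phi(r) = -int_{origin}^{r} H_p . dl`` along straight paths, by
    Gauss-Legendre quadrature.  Valid in a current-free, simply connected
    region containing ``origin`` and all ``points`` — i.e. inside a core
    that does not enclose any coil conductor.  The paths must not cross
    filaments.
    """
    from . import coil as cm

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = np.asarray(origin, dtype=float)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    x = 0.5 * (x + 1.0)  # map to [0, 1]
    w = 0.5 * w
    d = pts - origin
    phi = np.zeros(pts.shape[0])
    for xk, wk in zip(x, w):
        H = cm.primary_B(coil, origin + xk * d) / MU0
        phi -= wk * np.einsum("ij,ij->i", H, d)
    return phi


def charge_energy_and_inductance(solution: CoilCoreSolution) -> dict:
    """Core energy and inductance correction evaluated from the charges.

    ``U_s = -1/2 sum_f rho_f A_f phi_p(c_f)`` — algebraically equal to
    ``1/2 int M . B_p dV`` for a current-free core region, but conditioned
    on the (well-resolved) surface charges instead of the interior field.
    Preferred at high permeability, where ``H_p + H_s`` inside the core is
    a difference of nearly equal quantities.
    """
    if solution.I0 == 0:
        raise ValueError("inductance correction undefined at I0 = 0")
    f = solution.faces
    origin = (solution.mesh.centroids.mean(axis=0)
              if solution.mesh is not None else f.center.mean(axis=0))
    phi = coil_scalar_potential(solution.coil, f.center, origin)
    U_s = -0.5 * float(np.sum(solution.rho * f.area * phi))
    L_s = 2.0 * U_s / solution.I0**2
    return {"U_s": U_s, "L_s": L_s, "L_p": solution.L_p,
            "L_total": solution.L_p + L_s}
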