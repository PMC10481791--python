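"""Closed-form integrals of the Laplace kernel over flat triangles.

For a triangle T with unit normal ``n`` (right-handed with respect to the
stored vertex order) and a constant unit source density, the field-type
integral

    G(r) = int_T (r - r') / |r - r'|^3 dS'

splits into a normal part equal to the signed solid angle of T seen from r
(van Oosterom & Strackee) and an in-plane part given by per-edge line
potentials (surface divergence theorem):

    G(r) = Omega(r) n + sum_edges (s_i x n) * int_edge dl'/|r - r'|

with ``Omega > 0`` on the +n side.  Evaluation exactly in the face plane
returns the principal value (Omega = 0).  All functions are vectorized over
(triangle, point) pairs.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-300


def solid_angle(tri: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Signed solid angle of triangles (M,3,3) seen from points (M,3).

    Positive when the point lies on the side the right-handed normal of the
    vertex ordering points to.
    """
    R = tri - pts[:, None, :]
    r = np.linalg.norm(R, axis=2)
    r1, r2, r3 = r[:, 0], r[:, 1], r[:, 2]
    num = np.einsum("ij,ij->i", R[:, 0], np.cross(R[:, 1], R[:, 2]))
    den = (r1 * r2 * r3
           + np.einsum("ij,ij->i", R[:, 0], R[:, 1]) * r3
           + np.einsum("ij,ij->i", R[:, 1], R[:, 2]) * r1
           + np.einsum("ij,ij->i", R[:, 2], R[:, 0]) * r2)
    # van Oosterom-Strackee is positive for vertices counterclockwise as
    # seen *from* the point; our convention is positive on the +n side,
    # i.e. where the vertex order appears clockwise -- hence the sign flip.
    return -2.0 * np.arctan2(num, den)


def grad_integral(tri: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """G(r) = int_T (r - r')/|r - r'|^3 dS' for (triangle, point) pairs.

    ``tri``: (M, 3, 3) triangle vertices; ``pts``: (M, 3) points.  Returns
    (M, 3).  For points in the face plane the principal value is returned.
    """
    tri = np.asarray(tri, dtype=float)
    pts = np.asarray(pts, dtype=float)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    nvec = np.cross(e1, e2)
    nhat = nvec / np.maximum(np.linalg.norm(nvec, axis=1, keepdims=True), _EPS)

    # in-plane guard: treat tiny normal offsets as exactly in-plane (PV)
    size = np.sqrt(np.linalg.norm(nvec, axis=1) / 2.0)
    d = np.einsum("ij,ij->i", pts - tri[:, 0], nhat)
    in_plane = np.abs(d) < 1e-12 * np.maximum(size, _EPS)

    omega = solid_angle(tri, pts)
    omega = np.where(in_plane, 0.0, omega)
    G = omega[:, None] * nhat

    for a, b in ((0, 1), (1, 2), (2, 0)):
        A = tri[:, a]
        B = tri[:, b]
        L = np.linalg.norm(B - A, axis=1)
        shat = (B - A) / np.maximum(L, _EPS)[:, None]
        mhat = np.cross(shat, nhat)  # outward in-plane edge normal
        lm = np.einsum("ij,ij->i", A - pts, shat)
        lp = np.einsum("ij,ij->i", B - pts, shat)
        Ra = np.linalg.norm(A - pts, axis=1)
        Rb = np.linalg.norm(B - pts, axis=1)
        # ln((Rb + lp)/(Ra + lm)) with a stable branch when r lies beyond B
        num = Rb + lp
        den = Ra + lm
        alt = (Ra - lm) / np.maximum(Rb - lp, _EPS)
        ratio = np.where(den > 1e-14 * L, num / np.maximum(den, _EPS), alt)
        term = np.log(np.maximum(ratio, _EPS))
        # a point exactly on the edge line segment has a divergent edge
        # integral; clamp to keep NaNs out (caller should use near-field
        # handling there)
        term = np.where(np.isfinite(term), term, 0.0)
        G += mhat * term[:, None]
    return G


def centroid_grad(area: np.ndarray, center: np.ndarray, pts: np.ndarray
                  ) -> np.ndarray:
    """One-point (centroid) approximation of :func:`grad_integral`."""
    d = pts - center
    r3 = np.maximum(np.linalg.norm(d, axis=1) ** 3, _EPS)
    return area[:, None] * d / r3[:, None]
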