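"""Filament ("wire grid") coil models, primary fields, and inductance.

A coil is represented by many short straight current filaments.  Each
filament segment ``m`` carries the fraction ``w_m`` of the terminal current
``I0``; a Litz-wire conductor is modeled as a bundle of parallel filaments
with equal weights filling the conductor cross-section (uniform current
density).  All field kernels use the segment midpoint as a point source of
moment ``I0 * w_m * s_m`` (first-order rule; converges under segment
refinement).

Units are SI throughout: meters, amperes, tesla, henry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .materials import MU0


class SingularityError(ValueError):
    """An evaluation point coincides with a current filament."""


@dataclass
class FilamentCoil:
    """Straight-filament representation of a coil.

    Attributes
    ----------
    start, end:
        ``(N, 3)`` segment endpoints, meters.
    weight:
        ``(N,)`` fractional current ``i_m / I0`` per segment.
    I0:
        Terminal current, amperes.
    """

    start: np.ndarray
    end: np.ndarray
    weight: np.ndarray
    I0: float = 1.0
    n_parallel: int = 1  # parallel filaments per conductor cross-section

    def __post_init__(self):
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        self.end = np.atleast_2d(np.asarray(self.end, dtype=float))
        self.weight = np.atleast_1d(np.asarray(self.weight, dtype=float))
        if self.start.shape != self.end.shape or self.start.shape[0] != self.weight.size:
            raise ValueError("inconsistent filament array shapes")
        if np.any(self.lengths <= 0):
            raise ValueError("all filament segments must have positive length")

    @property
    def n_segments(self) -> int:
        return self.start.shape[0]

    @property
    def segments(self) -> np.ndarray:
        """Directed segment vectors s_m, (N, 3)."""
        return self.end - self.start

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.end - self.start, axis=1)

    @property
    def total_wire_length(self) -> float:
        return float(self.lengths.sum())

    def reversed(self) -> "FilamentCoil":
        return FilamentCoil(self.end.copy(), self.start.copy(),
                            self.weight.copy(), self.I0, self.n_parallel)

    def transformed(self, rotation=None, translation=None) -> "FilamentCoil":
        """Rigidly move the coil: ``r -> R r + t``."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        return FilamentCoil(self.start @ R.T + t, self.end @ R.T + t,
                            self.weight.copy(), self.I0, self.n_parallel)

    def __add__(self, other: "FilamentCoil") -> "FilamentCoil":
        if other.I0 != self.I0:
            raise ValueError("can only join coils with equal terminal current")
        return FilamentCoil(
            np.vstack([self.start, other.start]),
            np.vstack([self.end, other.end]),
            np.concatenate([self.weight, other.weight]),
            self.I0,
            max(self.n_parallel, other.n_parallel),
        )

    def to_csv(self, path) -> None:
        data = np.column_stack([self.start, self.end, self.weight])
        np.savetxt(path, data, delimiter=",",
                   header="x0,y0,z0,x1,y1,z1,weight", comments="")

    @staticmethod
    def from_csv(path, I0: float = 1.0) -> "FilamentCoil":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return FilamentCoil(data[:, 0:3], data[:, 3:6], data[:, 6], I0)


# ---------------------------------------------------------------------------
# Cross-section fill


def _disc_fill(n: int, radius: float) -> np.ndarray:
    """(n, 2) points quasi-uniformly filling a disc (sunflower layout)."""
    if n == 1 or radius == 0.0:
        return np.zeros((max(n, 1), 2))
    k = np.arange(n) + 0.5
    r = radius * np.sqrt(k / n)
    th = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _frames(tangent: np.ndarray):
    """Orthonormal (normal, binormal) frames for unit tangents (N, 3)."""
    t = tangent / np.linalg.norm(tangent, axis=1, keepdims=True)
    ref = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    n = np.cross(ref, t)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    b = np.cross(t, n)
    return n, b


def _centerline_to_coil(path: np.ndarray, conductor_radius: float,
                        n_filaments: int, I0: float,
                        twist_pitch: float | None = None,
                        closed: bool = False) -> FilamentCoil:
    """Expand a polyline centerline into a bundle of parallel filaments.

    Each filament is offset from the centerline inside the conductor
    cross-section; with ``twist_pitch`` the offsets rotate about the
    centerline by one turn per ``twist_pitch`` meters of arclength (twisted
    Litz bundle).
    """
    if closed:
        path = np.vstack([path, path[:1]])
    seg = np.diff(path, axis=0)
    mid_t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    # vertex tangents: average of adjacent segment tangents
    vt = np.vstack([mid_t[:1], mid_t[:-1] + mid_t[1:], mid_t[-1:]])
    if closed:
        vt[0] = vt[-1] = mid_t[0] + mid_t[-1]
    vt /= np.linalg.norm(vt, axis=1, keepdims=True)
    nrm, bnrm = _frames(vt)
    offsets = _disc_fill(n_filaments, conductor_radius)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    phase = 0.0 if not twist_pitch else 2.0 * np.pi * s / twist_pitch

    starts, ends = [], []
    for dx, dy in offsets:
        if twist_pitch:
            ox = dx * np.cos(phase) - dy * np.sin(phase)
            oy = dx * np.sin(phase) + dy * np.cos(phase)
        else:
            ox, oy = np.full(path.shape[0], dx), np.full(path.shape[0], dy)
        pts = path + ox[:, None] * nrm + oy[:, None] * bnrm
        starts.append(pts[:-1])
        ends.append(pts[1:])
    n_seg = path.shape[0] - 1
    weight = np.full(n_filaments * n_seg, 1.0 / n_filaments)
    return FilamentCoil(np.vstack(starts), np.vstack(ends), weight, I0,
                        n_parallel=n_filaments)


def circular_loop(radius: float, wire_radius: float = 0.0,
                  n_segments: int = 256, n_filaments: int = 1,
                  I0: float = 1.0, center=(0.0, 0.0, 0.0),
                  normal=(0.0, 0.0, 1.0)) -> FilamentCoil:
    """One circular turn of (optionally) finite wire cross-section.

    The conductor cross-section of radius ``wire_radius`` is filled with
    ``n_filaments`` parallel filaments carrying equal current (Litz-wire
    uniform current model).
    """
    if radius <= 0 or wire_radius < 0 or n_segments < 3 or n_filaments < 1:
        raise ValueError("loop dimensions and counts must be positive")
    th = np.linspace(0.0, 2.0 * np.pi, n_segments, endpoint=False)
    offsets = _disc_fill(n_filaments, wire_radius)
    starts, ends = [], []
    for dr, dz in offsets:
        r = radius + dr
        pts = np.column_stack([r * np.cos(th), r * np.sin(th),
                               np.full_like(th, dz)])
        starts.append(pts)
        ends.append(np.roll(pts, -1, axis=0))
    start = np.vstack(starts)
    end = np.vstack(ends)
    # orient the loop plane
    nz = np.asarray(normal, dtype=float)
    nz /= np.linalg.norm(nz)
    if not np.allclose(nz, [0, 0, 1]):
        nx = np.cross([0.0, 0.0, 1.0], nz)
        if np.linalg.norm(nx) < 1e-12:
            R = -np.eye(3) if nz[2] < 0 else np.eye(3)
            R[0, 0] = abs(R[0, 0])  # keep right-handed for the flip
        else:
            nx /= np.linalg.norm(nx)
            ang = np.arccos(np.clip(nz[2], -1, 1))
            K = np.array([[0, -nx[2], nx[1]], [nx[2], 0, -nx[0]],
                          [-nx[1], nx[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        start = start @ R.T
        end = end @ R.T
    c = np.asarray(center, dtype=float)
    weight = np.full(start.shape[0], 1.0 / n_filaments)
    return FilamentCoil(start + c, end + c, weight, I0, n_parallel=n_filaments)


def helical_spiral(radius: float, n_turns: int, pitch,
                   skew_angle: float = 0.0, bundle_radius: float = 0.0,
                   n_bundle_filaments: int = 1, twist_pitch: float | None = None,
                   segments_per_turn: int = 64, I0: float = 1.0,
                   phase: float = 0.0) -> FilamentCoil:
    """Helical-spiral winding of constant radius and per-turn pitch.

    Parameters
    ----------
    pitch:
        Axial advance per turn, meters: a scalar, or a per-turn sequence of
        length >= ``n_turns`` (variable-pitch winding).
    skew_angle:
        Tilt of the winding plane, radians: each point is sheared along x by
        ``z * tan(skew_angle)`` (matches a skewed winding template).
    bundle_radius, n_bundle_filaments, twist_pitch:
        Litz bundle cross-section radius, number of parallel strands, and
        optional twist (one full bundle rotation per ``twist_pitch`` meters
        of wire).
    phase:
        Azimuthal start angle, radians (e.g. pi to rotate a second winding
        by 180 degrees).
    """
    if radius <= 0 or n_turns < 1 or segments_per_turn < 8:
        raise ValueError("spiral dimensions and counts must be positive")
    pitch = np.atleast_1d(np.asarray(pitch, dtype=float))
    if pitch.size == 1:
        pitch = np.full(n_turns, pitch[0])
    if pitch.size < n_turns:
        raise ValueError("pitch profile shorter than the number of turns")
    pitch = pitch[:n_turns]
    if np.any(pitch < 0):
        raise ValueError("pitch must be non-negative")

    n_pts = n_turns * segments_per_turn + 1
    t = np.linspace(0.0, n_turns, n_pts)  # turn coordinate
    th = 2.0 * np.pi * t + phase
    z_turn = np.concatenate([[0.0], np.cumsum(pitch)])
    z = np.interp(t, np.arange(n_turns + 1), z_turn)
    x = radius * np.cos(th) + z * np.tan(skew_angle)
    y = radius * np.sin(th)
    path = np.column_stack([x, y, z])
    return _centerline_to_coil(path, bundle_radius, n_bundle_filaments, I0,
                               twist_pitch=twist_pitch)


def make_coil(spec: dict) -> FilamentCoil:
    """Build a coil from a declarative geometry spec (used by run configs).

    ``spec["type"]`` selects ``circular_loop`` or ``helical_spiral``; the
    remaining keys are passed to the builder.
    """
    spec = dict(spec)
    kind = spec.pop("type")
    builders = {"circular_loop": circular_loop, "helical_spiral": helical_spiral}
    if kind not in builders:
        raise ValueError(f"unknown coil spec type {kind!r}")
    return builders[kind](**spec)


# ---------------------------------------------------------------------------
# Litz bundle sizing

# Best-known circle-in-a-circle packing ratios r/R for n equal circles of
# radius r inside a container of radius R (Packomania / Graham et al.).
_PACKING_RATIO = {
    1: 1.0,
    2: 0.5,
    3: 0.464101615,
    4: 0.414213562,
    5: 0.370191908,
    6: 0.333333333,
    7: 0.333333333,
    8: 0.302593388,
    9: 0.276768654,
    10: 0.262258924,
    19: 0.205604647,
    37: 0.150892630,
    61: 0.117399779,
    100: 0.0902,
}


def litz_bundle_radius(single_wire_radius: float, n_wires: int) -> float:
    """Optimal Litz bundle (container) radius for ``n_wires`` strands.

    Uses a table of best-known circle-in-circle packing ratios; for n = 100
    the dimensionless strand radius is 0.0902, so 0.15 mm strands give a
    1.663 mm bundle.
    """
    if single_wire_radius <= 0:
        raise ValueError("wire radius must be positive")
    try:
        ratio = _PACKING_RATIO[int(n_wires)]
    except (KeyError, ValueError):
        raise ValueError(
            f"no packing ratio tabulated for n_wires={n_wires}; "
            f"supported counts: {sorted(_PACKING_RATIO)}"
        ) from None
    return single_wire_radius / ratio


# ---------------------------------------------------------------------------
# Field evaluation

_GUARD = 1e-9  # m; minimum allowed point-to-filament distance


def _field_sums(coil: FilamentCoil, points: np.ndarray, want_A: bool,
                want_B: bool, chunk: int = 2 ** 22):
    """Blocked direct summation of the midpoint filament kernels."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mids = coil.midpoints
    mom = coil.weight[:, None] * coil.segments  # w_m * s_m
    n_pts, n_seg = pts.shape[0], mids.shape[0]
    A = np.zeros((n_pts, 3)) if want_A else None
    B = np.zeros((n_pts, 3)) if want_B else None
    rows = max(1, chunk // max(n_seg, 1))
    for i0 in range(0, n_pts, rows):
        p = pts[i0:i0 + rows]
        d = p[:, None, :] - mids[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        rmin = np.sqrt(r2.min(axis=1))
        if np.any(rmin < _GUARD):
            j = int(np.argmin(rmin))
            raise SingularityError(
                f"evaluation point {p[j]} lies on a current filament"
            )
        inv_r = 1.0 / np.sqrt(r2)
        if want_A:
            A[i0:i0 + rows] = inv_r @ mom
        if want_B:
            inv_r3 = inv_r / r2
            cross = np.cross(mom[None, :, :], d)
            B[i0:i0 + rows] = np.einsum("ij,ijk->ik", inv_r3, cross)
    k = MU0 / (4.0 * np.pi) * coil.I0
    if want_A:
        A *= k
    if want_B:
        B *= k
    return A, B


def primary_fields(coil: FilamentCoil, points) -> dict:
    """Free-space coil fields at ``points``.

    Returns a dict with the magnetic vector potential ``A`` (V*s/m), flux
    density ``B`` (T), and field intensity ``H = B/mu0`` (A/m), each of
    shape ``(n_points, 3)``.
    """
    A, B = _field_sums(coil, points, want_A=True, want_B=True)
    return {"A": A, "B": B, "H": B / MU0}


def primary_A(coil: FilamentCoil, points) -> np.ndarray:
    return _field_sums(coil, points, want_A=True, want_B=False)[0]


def primary_B(coil: FilamentCoil, points) -> np.ndarray:
    return _field_sums(coil, points, want_A=False, want_B=True)[1]


def primary_E(coil: FilamentCoil, points, dIdt: float) -> np.ndarray:
    """Induced primary electric field E = -(dI/dt) * A / I0, V/m."""
    return (-dIdt / coil.I0) * primary_A(coil, points)


# ---------------------------------------------------------------------------
# Inductance (Neumann formula on filaments)


def _resolution_check(coil: FilamentCoil) -> None:
    """Advisory check of segment length vs inter-filament spacing.

    For precise Neumann-formula inductances the segment length should be
    comparable to (not far below) the typical distance between distinct
    filaments; a single infinitely thin loop has a log-divergent self term
    and its computed L grows with refinement.
    """
    if coil.n_parallel <= 1:
        warnings.warn(
            "self-inductance of a single infinitely-thin filament is "
            "mesh-dependent (log divergence with the omitted m = n terms); "
            "fill the conductor cross-section with parallel filaments",
            stacklevel=3,
        )
        return
    mids = coil.midpoints
    n = mids.shape[0]
    idx = np.random.default_rng(0).choice(n, size=min(n, 256), replace=False)
    d = np.linalg.norm(mids[idx][:, None, :] - mids[None, :, :], axis=2)
    d[d == 0] = np.inf
    spacing = float(np.median(d.min(axis=1)))
    if coil.lengths.mean() < spacing:
        warnings.warn(
            f"average segment length {coil.lengths.mean():.3g} m is below the "
            f"average filament spacing {spacing:.3g} m; Neumann inductance "
            "may be under-resolved",
            stacklevel=3,
        )


def self_inductance(coil: FilamentCoil, chunk: int = 2 ** 22) -> float:
    """Neumann-formula self-inductance, henry.

    ``L = mu0/4pi * sum_m | (w_m s_m) . sum_{n != m} w_n s_n / |r_m - r_n| |``
    with the diagonal terms set to zero; independent of I0.
    """
    if coil.n_segments < 2:
        raise ValueError("need at least 2 segments for an inductance")
    _resolution_check(coil)
    mids = coil.midpoints
    mom = coil.weight[:, None] * coil.segments
    n = mids.shape[0]
    total = 0.0
    rows = max(1, chunk // n)
    for i0 in range(0, n, rows):
        i1 = min(i0 + rows, n)
        d = mids[i0:i1, None, :] - mids[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        np.fill_diagonal(r[:, i0:i1], np.inf)  # omit m = n
        inner = (1.0 / r) @ mom
        total += np.abs(np.einsum("ik,ik->i", mom[i0:i1], inner)).sum()
    return MU0 / (4.0 * np.pi) * total


def mutual_inductance(coil_a: FilamentCoil, coil_b: FilamentCoil,
                      chunk: int = 2 ** 22) -> float:
    """Neumann-formula mutual inductance between two coils, henry.

    Symmetric in its arguments; raises :class:`SingularityError` if the
    filament clouds touch.
    """
    ma, mb = coil_a.midpoints, coil_b.midpoints
    sa = coil_a.weight[:, None] * coil_a.segments
    sb = coil_b.weight[:, None] * coil_b.segments
    total = 0.0
    rows = max(1, chunk // mb.shape[0])
    for i0 in range(0, ma.shape[0], rows):
        d = ma[i0:i0 + rows, None, :] - mb[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
        if r.min() < _GUARD:
            raise SingularityError("coil filaments intersect")
        total += np.einsum("ik,ij,jk->", sa[i0:i0 + rows], 1.0 / r, sb)
    return MU0 / (4.0 * np.pi) * total
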