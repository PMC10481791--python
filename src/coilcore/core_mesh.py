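"""Tetrahedral core meshes and the all-faces topology used by the solver.

The charge-based solver needs, besides the tetrahedra themselves, the set of
*unique* mesh faces — boundary and inner — each with an orientation (a
"plus" and a "minus" adjacent tetrahedron), area, center, and unit normal
pointing from plus to minus (outward on the boundary).

Primitive generators (cuboid, cylinder, C-shape, sphere) produce watertight,
conforming meshes deterministically: hexahedral cells are split with the
Kuhn 6-tet decomposition (face-conforming across identical neighboring
cells) and prisms with a centroid split whose quad diagonals follow the
minimum-global-vertex-index rule.  Coordinates are SI meters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MeshError(ValueError):
    pass


class NonManifoldError(MeshError):
    pass


@dataclass
class TetCoreMesh:
    """Tetrahedral volume mesh of a magnetic core.

    ``vertices``: (V, 3) float, meters; ``tets``: (T, 4) int.  Tetrahedra
    are re-oriented on construction so every signed volume is positive.
    """

    vertices: np.ndarray
    tets: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        v = self._signed_volumes()
        neg = v < 0
        if np.any(neg):
            self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]
            v = np.abs(v)
        scale = float(np.abs(v).max()) if v.size else 0.0
        if v.size == 0 or np.any(np.abs(v) <= 1e-12 * scale):
            raise MeshError("mesh contains degenerate (zero-volume) tetrahedra")

    def _signed_volumes(self) -> np.ndarray:
        p = self.vertices[self.tets]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    @property
    def volumes(self) -> np.ndarray:
        return np.abs(self._signed_volumes())

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def transformed(self, rotation=None, translation=None, scale=1.0
                    ) -> "TetCoreMesh":
        """Affine map of the mesh: ``r -> scale * R r + t``."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return TetCoreMesh(scale * self.vertices @ R.T + t, self.tets.copy())

    def tet_neighbors(self):
        """List of face-adjacent tet indices per tet (from the face set)."""
        fs = build_faces(self)
        nbrs = [[] for _ in range(self.n_tets)]
        inner = ~fs.is_boundary
        for p, m in zip(fs.plus_tet[inner], fs.minus_tet[inner]):
            nbrs[p].append(m)
            nbrs[m].append(p)
        return nbrs


@dataclass
class FaceSet:
    """Unique oriented faces of a tet mesh (boundary and inner).

    ``normal`` is the unit normal pointing from the ``plus_tet`` toward the
    ``minus_tet`` (outward on boundary faces, where ``minus_tet`` is -1).
    ``tri`` holds the face vertex coordinates, shape (F, 3, 3), for the
    analytic panel integrals.
    """

    faces: np.ndarray          # (F, 3) vertex indices
    tri: np.ndarray            # (F, 3, 3) vertex coordinates
    normal: np.ndarray         # (F, 3)
    area: np.ndarray           # (F,)
    center: np.ndarray         # (F, 3)
    plus_tet: np.ndarray       # (F,)
    minus_tet: np.ndarray      # (F,), -1 on the boundary
    is_boundary: np.ndarray    # (F,) bool
    tet_faces: np.ndarray | None = None  # (T, 4) face ids per tet (full sets)

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def subset(self, mask) -> "FaceSet":
        mask = np.asarray(mask)
        return FaceSet(self.faces[mask], self.tri[mask], self.normal[mask],
                       self.area[mask], self.center[mask], self.plus_tet[mask],
                       self.minus_tet[mask], self.is_boundary[mask])

    def boundary(self) -> "FaceSet":
        return self.subset(self.is_boundary)

    def transformed(self, rotation=None, translation=None) -> "FaceSet":
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return FaceSet(self.faces, self.tri @ R.T + t, self.normal @ R.T,
                       self.area, self.center @ R.T + t, self.plus_tet,
                       self.minus_tet, self.is_boundary)

    def verify(self) -> None:
        """Check closure and orientability of the boundary surface."""
        b = self.boundary()
        net = (b.area[:, None] * b.normal).sum(axis=0)
        if np.linalg.norm(net) > 1e-12 * b.area.sum():
            raise MeshError("boundary surface is not closed: net area-normal "
                            f"= {net}")
        edges = np.sort(
            b.faces[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts != 2):
            raise NonManifoldError(
                "boundary is not a closed 2-manifold: "
                f"{int((counts != 2).sum())} edges not shared by exactly 2 faces")


def build_faces(mesh: TetCoreMesh) -> FaceSet:
    """Unique-face topology with plus/minus orientation.

    The plus tet is the one with the lower index (its choice is arbitrary
    for the physics; the solution is invariant under relabeling).  Boundary
    faces take the single interior tet as plus, normal outward.
    """
    tets = mesh.tets
    local = tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
    all_faces = local.reshape(-1, 3)
    key = np.sort(all_faces, axis=1)
    uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                      return_counts=True)
    if np.any(counts > 2):
        raise NonManifoldError(
            f"{int((counts > 2).sum())} faces are shared by more than 2 tets")
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    order = np.argsort(inverse, kind="stable")
    f_sorted = inverse[order]
    t_sorted = owner[order]
    starts = np.searchsorted(f_sorted, np.arange(uniq.shape[0]))
    plus = t_sorted[starts]
    minus = np.full(uniq.shape[0], -1, dtype=np.int64)
    two = counts == 2
    second = t_sorted[starts[two] + 1]
    first = plus[two]
    plus_two = np.minimum(first, second)
    minus[two] = np.maximum(first, second)
    plus[two] = plus_two

    tri = mesh.vertices[uniq]
    cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nrm = np.linalg.norm(cr, axis=1)
    if np.any(nrm <= 0):
        raise MeshError("degenerate (zero-area) face")
    normal = cr / nrm[:, None]
    center = tri.mean(axis=1)
    plus_cent = mesh.vertices[tets[plus]].mean(axis=1)
    flip = np.einsum("ij,ij->i", normal, center - plus_cent) < 0
    normal[flip] = -normal[flip]
    # keep the stored vertex order consistent with the normal (CCW about it)
    uniq = uniq.copy()
    uniq[flip] = uniq[flip][:, [0, 2, 1]]
    tri = mesh.vertices[uniq]
    return FaceSet(uniq, tri, normal, nrm / 2.0, center, plus,
                   minus, counts == 1,
                   tet_faces=inverse.reshape(mesh.n_tets, 4))


# ---------------------------------------------------------------------------
# Primitive generators

# Kuhn (Freudenthal) decomposition: 6 tets per hex cell, each following a
# monotone vertex path 000 -> 111; conforming across translated cells.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_tets(nx: int, ny: int, nz: int, keep=None) -> np.ndarray:
    """Tets of a structured (nx, ny, nz)-cell grid; vertex id = i*(ny+1)*(nz+1)+j*(nz+1)+k."""

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cells = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    if keep is not None:
        cells = cells[keep.ravel()]
    tets = []
    for perm in _KUHN_PERMS:
        steps = np.zeros((4, 3), dtype=int)
        for s, ax in enumerate(perm):
            steps[s + 1] = steps[s]
            steps[s + 1, ax] += 1
        corners = [vid(cells[:, 0] + dx, cells[:, 1] + dy, cells[:, 2] + dz)
                   for dx, dy, dz in steps]
        tets.append(np.column_stack(corners))
    return np.vstack(tets)


def _compact(vertices: np.ndarray, tets: np.ndarray):
    used = np.unique(tets)
    remap = np.full(vertices.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    return vertices[used], remap[tets]


def _cuboid(size, divisions) -> TetCoreMesh:
    lx, ly, lz = size
    nx, ny, nz = divisions
    if min(lx, ly, lz) <= 0 or min(nx, ny, nz) < 1:
        raise MeshError("cuboid dimensions and divisions must be positive")
    x = np.linspace(0, lx, nx + 1)
    y = np.linspace(0, ly, ny + 1)
    z = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return TetCoreMesh(verts, _kuhn_tets(nx, ny, nz))


def _grid_coords(breaks, h: float) -> np.ndarray:
    """Coordinate lines covering ``breaks`` exactly, max spacing ~h."""
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((b - a) / h)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def _c_shape(outer, thickness, gap, depth, cell_size) -> TetCoreMesh:
    """Rectangular frame (picture-frame) core with a gap in the top bar."""
    lx, ly = outer
    t, g, lz = thickness, gap, depth
    if min(lx, ly, lz, t) <= 0 or g < 0 or 2 * t >= min(lx, ly) or g > lx - 2 * t:
        raise MeshError("degenerate C-shape dimensions")
    xb = sorted({0.0, t, lx / 2 - g / 2, lx / 2 + g / 2, lx - t, lx})
    yb = sorted({0.0, t, ly - t, ly})
    x = _grid_coords(xb, cell_size)
    y = _grid_coords(yb, cell_size)
    z = _grid_coords([0.0, lz], cell_size)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    cx = 0.5 * (x[:-1] + x[1:])
    cy = 0.5 * (y[:-1] + y[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    in_hole = ((CX > t) & (CX < lx - t) & (CY > t) & (CY < ly - t))
    in_gap = ((CY > ly - t) & (np.abs(CX - lx / 2) < g / 2)) if g > 0 else False
    keep2d = ~(in_hole | in_gap)
    keep = np.repeat(keep2d[:, :, None], z.size - 1, axis=2)
    tets = _kuhn_tets(x.size - 1, y.size - 1, z.size - 1, keep=keep)
    return TetCoreMesh(*_compact(verts, tets))


def _split_quad(a, b, B, A):
    """Split quad (a, b, B, A) into 2 triangles by the min-index diagonal."""
    if min(a, B) < min(b, A):  # diagonal a-B
        return [(a, b, B), (a, B, A)]
    return [(a, b, A), (b, B, A)]


def _cylinder(radius, height, n_azimuthal=32, n_radial=3, n_layers=4
              ) -> TetCoreMesh:
    """n-gon prism stack: disc triangulation extruded and split into tets."""
    if radius <= 0 or height <= 0 or n_azimuthal < 3 or n_radial < 1 \
            or n_layers < 1:
        raise MeshError("cylinder dimensions must be positive")
    n, K, L = n_azimuthal, n_radial, n_layers
    # 2-D disc: center + K rings of n points
    pts2d = [(0.0, 0.0)]
    for k in range(1, K + 1):
        r = radius * k / K
        th = 2 * np.pi * np.arange(n) / n
        pts2d.extend(zip(r * np.cos(th), r * np.sin(th)))
    pts2d = np.asarray(pts2d)
    nv2d = pts2d.shape[0]

    def ring(k, i):
        return 1 + (k - 1) * n + (i % n)

    tris = [(0, ring(1, i), ring(1, i + 1)) for i in range(n)]
    for k in range(1, K):
        for i in range(n):
            a, b = ring(k, i), ring(k, i + 1)
            A, B = ring(k + 1, i), ring(k + 1, i + 1)
            tris.extend(_split_quad(a, b, B, A))
    tris = np.asarray(tris)

    zs = np.linspace(0, height, L + 1)
    verts = np.concatenate(
        [np.column_stack([pts2d[:, 0], pts2d[:, 1], np.full(nv2d, z)])
         for z in zs])
    n_base = verts.shape[0]
    tets = []
    cents = []
    cid = n_base
    for layer in range(L):
        lo, hi = layer * nv2d, (layer + 1) * nv2d
        for p, q, s in tris:
            a, b, c = lo + p, lo + q, lo + s
            A, B, C = hi + p, hi + q, hi + s
            cents.append(verts[[a, b, c, A, B, C]].mean(axis=0))
            faces = [(a, c, b), (A, B, C)]
            faces += _split_quad(a, b, B, A)
            faces += _split_quad(b, c, C, B)
            faces += _split_quad(c, a, A, C)
            for f in faces:
                tets.append((cid, *f))
            cid += 1
    verts = np.vstack([verts, np.asarray(cents)])
    return TetCoreMesh(verts, np.asarray(tets))


def sphere_mesh(radius: float, n: int = 8) -> TetCoreMesh:
    """Sphere tet mesh via a cube-to-ball map of a Kuhn-split cube grid.

    Vertices on nested cubes (inf-norm shells) map to nested spheres;
    boundary vertices land exactly on the sphere of the given radius.
    """
    if radius <= 0 or n < 2:
        raise MeshError("sphere radius and resolution must be positive")
    g = np.linspace(-1, 1, n + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    p = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    s = np.max(np.abs(p), axis=1)
    e = np.linalg.norm(p, axis=1)
    scale = np.zeros_like(s)
    nz = e > 0
    scale[nz] = radius * s[nz] / e[nz]
    verts = p * scale[:, None]
    return TetCoreMesh(verts, _kuhn_tets(n, n, n))


def generate_primitive(shape: str, **dims) -> TetCoreMesh:
    """Built-in watertight tet meshes for simple core shapes.

    ``shape`` is one of ``cuboid`` (size, divisions), ``cylinder`` (radius,
    height, n_azimuthal, n_radial, n_layers), ``c_shape`` (outer, thickness,
    gap, depth, cell_size) or ``sphere`` (radius, n).
    """
    builders = {"cuboid": _cuboid, "cylinder": _cylinder,
                "c_shape": _c_shape, "sphere": sphere_mesh}
    if shape not in builders:
        raise MeshError(f"unknown primitive shape {shape!r}")
    return builders[shape](**dims)


# ---------------------------------------------------------------------------
# STL import and external tet meshes


def import_stl(path, scale: float = 1.0, target_edge: float | None = None
               ) -> TetCoreMesh:
    """Import a watertight STL surface and tetrahedralize its interior.

    The surface vertices are combined with an interior point lattice
    (spacing ``target_edge``, default the median surface edge length) and a
    Delaunay tetrahedralization is filtered to tets whose centroid lies
    inside the surface.  ``scale`` converts the file units to meters (e.g.
    1e-3 for a millimeter STL).

    A non-watertight surface raises :class:`MeshError` with the open-edge
    diagnostic.
    """
    import trimesh
    from scipy.spatial import Delaunay, cKDTree

    surf = trimesh.load_mesh(path)
    if not isinstance(surf, trimesh.Trimesh):
        raise MeshError(f"could not read a triangle surface from {path}")
    surf.apply_scale(scale)
    if not surf.is_watertight:
        edges = np.sort(surf.edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        open_edges = uniq[counts == 1]
        raise MeshError(
            f"STL surface is not watertight: {open_edges.shape[0]} open "
            f"edges, e.g. vertex pairs {open_edges[:5].tolist()}")
    if target_edge is None:
        target_edge = float(np.median(surf.edges_unique_length))
    tri = np.asarray(surf.triangles, dtype=float)
    lo, hi = surf.bounds
    axes = [np.arange(lo[i] + target_edge / 2, hi[i], target_edge)
            for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    if grid.shape[0]:
        # a deterministic jitter breaks the lattice degeneracies that
        # produce sliver tets in the Delaunay step
        rng = np.random.default_rng(1234)
        grid = grid + rng.normal(scale=0.08 * target_edge, size=grid.shape)
        inside = _winding_inside(tri, grid)
        # keep interior points clear of the surface to avoid slivers
        tree = cKDTree(np.vstack([surf.vertices, tri.mean(axis=1)]))
        d, _ = tree.query(grid[inside])
        interior = grid[inside][d > 0.45 * target_edge]
    else:
        interior = np.empty((0, 3))
    pts = np.vstack([surf.vertices, interior])
    dela = Delaunay(pts)
    cent = pts[dela.simplices].mean(axis=1)
    keep = _winding_inside(tri, cent)
    return TetCoreMesh(*_compact(pts, dela.simplices[keep]))


def _winding_inside(tri: np.ndarray, pts: np.ndarray,
                    chunk: int = 2 ** 22) -> np.ndarray:
    """Generalized winding number test for a closed triangle surface."""
    from ._triangle import solid_angle

    n_tri = tri.shape[0]
    omega = np.zeros(pts.shape[0])
    rows = max(1, chunk // max(n_tri, 1))
    for i0 in range(0, pts.shape[0], rows):
        p = pts[i0:i0 + rows]
        npts = p.shape[0]
        t = np.broadcast_to(tri[None], (npts, n_tri, 3, 3)).reshape(-1, 3, 3)
        pp = np.repeat(p, n_tri, axis=0)
        omega[i0:i0 + npts] = solid_angle(t, pp).reshape(npts, n_tri).sum(axis=1)
    return np.abs(omega) > 2.0 * np.pi


def read_tet_mesh(node_path, ele_path=None) -> TetCoreMesh:
    """Read an externally produced tet mesh in TetGen node/ele format."""
    node_path = str(node_path)
    if ele_path is None:
        if not node_path.endswith(".node"):
            raise MeshError("expected a .node file (with a matching .ele)")
        ele_path = node_path[:-5] + ".ele"

    def _rows(p):
        with open(p) as fh:
            rows = [ln.split() for ln in fh
                    if ln.strip() and not ln.lstrip().startswith("#")]
        return rows

    nrows = _rows(node_path)
    nv = int(nrows[0][0])
    ids = np.array([int(r[0]) for r in nrows[1:1 + nv]])
    verts = np.array([[float(x) for x in r[1:4]] for r in nrows[1:1 + nv]])
    erows = _rows(ele_path)
    nt = int(erows[0][0])
    tets = np.array([[int(x) for x in r[1:5]] for r in erows[1:1 + nt]])
    tets = tets - ids.min()  # 1- or 0-based indexing
    return TetCoreMesh(verts, tets)


def write_tet_mesh(mesh: TetCoreMesh, node_path) -> None:
    node_path = str(node_path)
    if not node_path.endswith(".node"):
        raise MeshError("node_path must end in .node")
    with open(node_path, "w") as fh:
        fh.write(f"{mesh.vertices.shape[0]} 3 0 0\n")
        for i, v in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
    with open(node_path[:-5] + ".ele", "w") as fh:
        fh.write(f"{mesh.n_tets} 4 0\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")


# ---------------------------------------------------------------------------
# VTK legacy ASCII output


def _vtk_header(fh, title: str):
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(title + "\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _vtk_data(fh, prefix: str, n: int, data: dict):
    first = True
    for name, arr in data.items():
        arr = np.asarray(arr)
        if first:
            fh.write(f"{prefix} {n}\n")
            first = False
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.9g")
        else:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.9g")


def write_vtk(mesh: TetCoreMesh, path, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write the tet mesh (and per-tet fields) as a legacy ASCII VTK file."""
    with open(path, "w") as fh:
        _vtk_header(fh, "coilcore tetrahedral core mesh")
        fh.write(f"POINTS {mesh.vertices.shape[0]} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.9g")
        fh.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(mesh.n_tets, 4), mesh.tets]), fmt="%d")
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10), fmt="%d")
        if cell_data:
            _vtk_data(fh, "CELL_DATA", mesh.n_tets, cell_data)
        if point_data:
            _vtk_data(fh, "POINT_DATA", mesh.vertices.shape[0], point_data)


def write_vtk_surface(faces: FaceSet, vertices: np.ndarray, path,
                      cell_data: dict | None = None) -> None:
    """Write a face set (e.g. with charge density) as triangles in VTK."""
    with open(path, "w") as fh:
        _vtk_header(fh, "coilcore face set")
        fh.write(f"POINTS {vertices.shape[0]} double\n")
        np.savetxt(fh, vertices, fmt="%.9g")
        n = faces.n_faces
        fh.write(f"CELLS {n} {n * 4}\n")
        np.savetxt(fh, np.column_stack([np.full(n, 3), faces.faces]), fmt="%d")
        fh.write(f"CELL_TYPES {n}\n")
        np.savetxt(fh, np.full(n, 5), fmt="%d")
        if cell_data:
            _vtk_data(fh, "CELL_DATA", n, cell_data)
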