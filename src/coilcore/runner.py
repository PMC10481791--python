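"""Configuration-driven runs: build coil + core + material, solve, report.

A :class:`RunConfig` is a plain serializable description (YAML-friendly
nested dicts, SI units) from which a run is fully reproducible.  Three
built-in fixtures cover the validation geometries used throughout the test
suite:

``loop_cylinder``
    A solid cylindrical core symmetrically inside a loose one-turn Litz
    loop — the classic saturation benchmark.  Dimensions are this package's
    own (documented here): core radius 10 mm, height 40 mm; loop radius
    25 mm, conductor radius 2 mm, coaxial and centered.
``sphere_uniform``
    A sphere in the nearly uniform field of a large Helmholtz-style coil
    pair — the analytic magnetizable-sphere oracle.
``rat_coil_like``
    Two 20-turn skewed helical spirals (radii 9 mm and 16 mm, the outer
    rotated by 180 degrees, total winding length 110 mm, 15-degree skew)
    with an optional 6-turn booster and a square-bar core.  The pitch
    profile tapers linearly (7.5 -> 3.5 mm over 20 turns); the real coil's
    exact profile is not public, so this fixture documents its own
    dimensions rather than reproducing a specific prototype.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field as dfield

import numpy as np
import yaml

from . import coil as coil_mod
from . import core_mesh
from .bem_linear import solve_linear_core
from .materials import AnhystereticCurve, fit_curve, preset_material
from .nonlinear import BemWorkspace, solve_nonlinear_core


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Fully serializable description of one coil + core solve."""

    coil: dict
    core: dict | None = None
    material: dict | None = None
    drive: dict = dfield(default_factory=lambda: {"I0": 1.0, "dIdt": 0.0})
    solver: dict = dfield(default_factory=dict)
    probes: list = dfield(default_factory=list)
    output: dict = dfield(default_factory=dict)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_yaml(source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        try:
            return RunConfig(**data)
        except TypeError as err:
            raise ConfigError(f"invalid run config: {err}") from None


def build_coil(spec: dict, I0: float) -> coil_mod.FilamentCoil:
    spec = dict(spec)
    parts = spec.pop("windings", None)
    if parts is not None:
        coils = [coil_mod.make_coil({**p, "I0": I0}) for p in parts]
        out = coils[0]
        for c in coils[1:]:
            out = out + c
        return out
    if "csv" in spec:
        return coil_mod.FilamentCoil.from_csv(spec["csv"], I0=I0)
    spec["I0"] = I0
    return coil_mod.make_coil(spec)


def build_core(spec: dict | None) -> core_mesh.TetCoreMesh | None:
    if spec is None:
        return None
    spec = dict(spec)
    if "stl" in spec:
        return core_mesh.import_stl(spec["stl"], scale=spec.get("scale", 1e-3),
                                    target_edge=spec.get("target_edge"))
    if "node" in spec:
        return core_mesh.read_tet_mesh(spec["node"])
    shape = spec.pop("primitive")
    translation = spec.pop("translation", None)
    mesh = core_mesh.generate_primitive(shape, **spec)
    if translation is not None:
        mesh = mesh.transformed(translation=np.asarray(translation, float))
    return mesh


def build_material(spec: dict | None):
    """Returns an AnhystereticCurve, a linear mu_r float, or None (no core)."""
    if spec is None:
        return None
    if "preset" in spec:
        return preset_material(spec["preset"])
    if "linear_mu_r" in spec:
        return float(spec["linear_mu_r"])
    if "loci_csv" in spec:
        loci = np.loadtxt(spec["loci_csv"], delimiter=",", ndmin=2)
        return fit_curve(loci, spec.get("kind", "froelich"))
    if "kind" in spec:
        return AnhystereticCurve(spec["kind"], spec["a1"], spec["a2"])
    raise ConfigError(f"cannot interpret material spec {spec!r}")


def run_solve(config: RunConfig, workspace: BemWorkspace | None = None,
              verbose: bool = False):
    """Execute a config end to end.

    Returns ``(solution, report)``.  The report dict carries the inductance
    summary, core permeability statistics, convergence history and timing;
    rerunning an identical config reproduces it bit-identically (the whole
    pipeline is deterministic).
    """
    t0 = time.perf_counter()
    solver = dict(config.solver)
    backend = solver.pop("backend", "direct")
    if backend != "direct":
        raise ConfigError(
            f"unknown matvec backend {backend!r}; available: 'direct'")
    I0 = float(config.drive.get("I0", 1.0))
    dIdt = float(config.drive.get("dIdt", 0.0))
    coil = build_coil(config.coil, I0)
    mesh = build_core(config.core)
    material = build_material(config.material)

    report = {"I0": I0, "dIdt": dIdt, "n_segments": coil.n_segments}
    if mesh is None or material is None or (
            isinstance(material, float) and material == 1.0):
        # free-space coil (or a vacuum "core"): primary quantities only
        from .fields import CoilCoreSolution
        if mesh is not None:
            faces = core_mesh.build_faces(mesh).boundary()
            sol = CoilCoreSolution(coil=coil, mesh=mesh, faces=faces,
                                   rho=np.zeros(faces.n_faces), I0=I0,
                                   mu_r=np.ones(mesh.n_tets),
                                   H_total=coil_mod.primary_B(
                                       coil, mesh.centroids) / 4e-7 / np.pi,
                                   M=np.zeros((mesh.n_tets, 3)))
            ind = sol.core_energy_and_inductance()
        else:
            sol = CoilCoreSolution(coil=coil, faces=None, rho=np.zeros(0),
                                   I0=I0)
            ind = {"U_s": 0.0, "L_s": 0.0, "L_p": sol.L_p,
                   "L_total": sol.L_p}
        report.update(L_p=ind["L_p"], L_s=ind["L_s"], L_total=ind["L_total"],
                      mu_mean=1.0)
    elif isinstance(material, float):
        sol = solve_linear_core(mesh, material, coil,
                                tol=solver.get("gmres_tol", 1e-8),
                                max_iter=solver.get("gmres_max_iter", 300))
        ind = sol.core_energy_and_inductance()
        report.update(L_p=ind["L_p"], L_s=ind["L_s"], L_total=ind["L_total"],
                      U_s=ind["U_s"], mu_mean=material,
                      n_tets=mesh.n_tets, n_faces=sol.faces.n_faces,
                      gmres_iterations=sol.solve_info["iterations"])
    else:
        sol, log = solve_nonlinear_core(
            mesh, material, coil,
            alpha=solver.get("alpha", 0.4),
            beta=solver.get("beta", 0.0),
            tol_e1=solver.get("tol_e1", 1e-3),
            tol_e2=solver.get("tol_e2", 5e-3),
            max_iter=solver.get("max_iter", 30),
            workspace=workspace, verbose=verbose)
        ind = sol.core_energy_and_inductance()
        report.update(L_p=ind["L_p"], L_s=ind["L_s"], L_total=ind["L_total"],
                      U_s=ind["U_s"],
                      mu_mean=float(np.mean(sol.mu_r)),
                      mu_min=float(np.min(sol.mu_r)),
                      mu_max=float(np.max(sol.mu_r)),
                      n_tets=mesh.n_tets, n_faces=sol.faces.n_faces,
                      iterations=len(log.e1), e1=log.e1, e2=log.e2,
                      gmres_iterations=log.gmres_iterations)
    if config.probes:
        pts = np.asarray(config.probes, dtype=float).reshape(-1, 3)
        report["probe_points"] = pts.tolist()
        report["probe_E"] = sol.total_E(pts, dIdt).tolist() if dIdt else None
        report["probe_A"] = sol.total_vector_potential(pts).tolist()
    report["wall_time_s"] = time.perf_counter() - t0

    out = config.output or {}
    if out.get("vtk") and mesh is not None:
        core_mesh.write_vtk(mesh, out["vtk"], cell_data={
            "mu_r": sol.mu_r, "M": sol.M, "H": sol.H_total})
    return sol, report


def line_probe(start, end, n: int) -> np.ndarray:
    """n evenly spaced observation points from start to end (inclusive)."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    return start + t * (end - start)


def grid_probe(center, size, n: int, normal="z") -> np.ndarray:
    """n x n planar grid of observation points.

    ``size`` is the full edge length of the square patch centered at
    ``center``; ``normal`` picks the plane orientation (``"x"``, ``"y"``
    or ``"z"``).
    """
    u = np.linspace(-0.5, 0.5, n) * size
    A, B = np.meshgrid(u, u, indexing="ij")
    zero = np.zeros_like(A)
    comps = {"x": (zero, A, B), "y": (A, zero, B), "z": (A, B, zero)}
    pts = np.stack(comps[normal], axis=-1).reshape(-1, 3)
    return pts + np.asarray(center, dtype=float)


# ---------------------------------------------------------------------------
# Fixtures

_RES = {"coarse": 0.5, "default": 1.0, "fine": 1.6}


def make_fixture(name: str, resolution: str = "default",
                 material: dict | None = None, I0: float = 1.0,
                 dIdt: float = 0.0, booster: bool = False) -> RunConfig:
    """Built-in validation configurations (see module docstring)."""
    if resolution not in _RES:
        raise ConfigError(f"unknown resolution {resolution!r}")
    s = _RES[resolution]
    if name == "loop_cylinder":
        return RunConfig(
            coil={"type": "circular_loop", "radius": 25e-3,
                  "wire_radius": 2e-3, "n_segments": int(128 * s) ,
                  "n_filaments": 12},
            core={"primitive": "cylinder", "radius": 10e-3, "height": 40e-3,
                  "n_azimuthal": max(6, int(14 * s)),
                  "n_radial": max(2, int(4 * s)),
                  "n_layers": max(3, int(7 * s)),
                  "translation": [0.0, 0.0, -20e-3]},
            material=material or {"preset": 2},
            drive={"I0": I0, "dIdt": dIdt},
        )
    if name == "sphere_uniform":
        return RunConfig(
            coil={"windings": [
                {"type": "circular_loop", "radius": 0.5, "n_segments": 128,
                 "center": [0.0, 0.0, -0.25]},
                {"type": "circular_loop", "radius": 0.5, "n_segments": 128,
                 "center": [0.0, 0.0, 0.25]},
            ]},
            core={"primitive": "sphere", "radius": 25e-3,
                  "n": max(4, int(8 * s))},
            material=material or {"linear_mu_r": 3.0},
            drive={"I0": I0, "dIdt": dIdt},
        )
    if name == "rat_coil_like":
        pitch = np.linspace(7.5e-3, 3.5e-3, 20).tolist()  # sums to 110 mm
        windings = [
            {"type": "helical_spiral", "radius": 9e-3, "n_turns": 20,
             "pitch": pitch, "skew_angle": np.deg2rad(15.0),
             "bundle_radius": 2e-3, "n_bundle_filaments": max(4, int(7 * s)),
             "twist_pitch": 40e-3,
             "segments_per_turn": max(24, int(48 * s))},
            {"type": "helical_spiral", "radius": 16e-3, "n_turns": 20,
             "pitch": pitch, "skew_angle": np.deg2rad(15.0),
             "bundle_radius": 2e-3, "n_bundle_filaments": max(4, int(7 * s)),
             "twist_pitch": 40e-3, "phase": np.pi,
             "segments_per_turn": max(24, int(48 * s))},
        ]
        if booster:
            windings.append(
                {"type": "helical_spiral", "radius": 16e-3, "n_turns": 6,
                 "pitch": 5.5e-3, "skew_angle": np.deg2rad(15.0),
                 "bundle_radius": 2e-3,
                 "n_bundle_filaments": max(4, int(7 * s)),
                 "twist_pitch": 40e-3,
                 "segments_per_turn": max(24, int(48 * s))})
        n_xy = max(2, int(3 * s))
        return RunConfig(
            coil={"windings": windings},
            core={"primitive": "cuboid", "size": [8e-3, 8e-3, 150e-3],
                  "divisions": [n_xy, n_xy, max(12, int(24 * s))],
                  "translation": [-4e-3, -4e-3, -20e-3]},
            material=material or {"preset": 2},
            drive={"I0": I0, "dIdt": dIdt},
        )
    raise ConfigError(f"unknown fixture {name!r}")
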