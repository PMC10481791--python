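"""Shared fixtures: all geometry is generated programmatically at test time.

The expensive solves (uniform-field sphere, loop + cylinder saturation
runs) are session-scoped so the closed-form comparisons, invariant checks
and acceptance tests reuse one solution each.
"""

import numpy as np
import pytest

import coilcore as cc
from coilcore.nonlinear import BemWorkspace
from coilcore.runner import build_coil, build_core


SPHERE_RADIUS = 0.025
SPHERE_MU_R = 3.0


@pytest.fixture(scope="session")
def helmholtz():
    """Large coaxial loop pair: ~uniform axial field at the origin."""
    c = (cc.circular_loop(0.5, n_segments=128, center=(0, 0, -0.25), I0=100.0)
         + cc.circular_loop(0.5, n_segments=128, center=(0, 0, 0.25), I0=100.0))
    return c


@pytest.fixture(scope="session")
def applied_H0(helmholtz):
    return cc.primary_B(helmholtz, [[0.0, 0.0, 0.0]])[0] / cc.MU0


@pytest.fixture(scope="session")
def sphere_solution(helmholtz):
    """Linear mu_r = 3 sphere in the uniform field: the classical oracle."""
    mesh = cc.sphere_mesh(SPHERE_RADIUS, 20)
    return cc.solve_linear_core(mesh, SPHERE_MU_R, helmholtz)


@pytest.fixture(scope="session")
def small_loop():
    """R = 10 mm loop of 1 mm wire, cross-section filled with filaments.

    128 segments keep the segment length comparable to the filament
    spacing, which the Neumann-formula resolution guidance asks for.
    """
    return cc.circular_loop(0.01, 0.001, n_segments=128, n_filaments=25,
                            I0=1.0)


@pytest.fixture(scope="session")
def coarse_cylinder():
    """Small loop + cylinder-core problem for fast nonlinear unit tests."""
    cfg = cc.make_fixture("loop_cylinder", resolution="coarse", I0=20e3)
    coil = build_coil(cfg.coil, 20e3)
    mesh = build_core(cfg.core)
    ws = BemWorkspace(mesh, None, coil)
    return {"coil": coil, "mesh": mesh, "ws": ws, "faces": ws.faces}


@pytest.fixture(scope="session")
def full_cylinder():
    """The ~5500-tet loop + cylinder fixture used for the saturation and
    convergence acceptance checks (workspace and nonlinear solutions are
    shared across materials and tests)."""
    cfg = cc.make_fixture("loop_cylinder", I0=20e3)
    coil = build_coil(cfg.coil, 20e3)
    mesh = build_core(cfg.core)
    ws = BemWorkspace(mesh, None, coil)
    cache = {}

    def solve(mat: int, I0: float = 20e3):
        key = (mat, I0)
        if key not in cache:
            wsI = ws if I0 == 20e3 else ws.with_current(I0)
            cache[key] = cc.solve_nonlinear_core(
                mesh, cc.preset_material(mat), wsI.coil, workspace=wsI,
                max_iter=30)
        return cache[key]

    return {"coil": coil, "mesh": mesh, "ws": ws, "faces": ws.faces,
            "solve": solve}


def dipole_H(m, points):
    """Point-dipole field H(r) = (3 r(r.m) - m r^2)/(4 pi r^5)."""
    points = np.atleast_2d(points)
    r = np.linalg.norm(points, axis=1)
    rhat = points / r[:, None]
    return ((3.0 * rhat * (rhat @ m)[:, None] - m[None, :])
            / (4.0 * np.pi * r[:, None] ** 3))
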