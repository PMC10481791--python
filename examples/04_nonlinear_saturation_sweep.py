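"""Nonlinear core saturation: a cylinder inside a one-turn loop.

Sweeps the terminal current from the small-signal regime to TMS-level
drive and prints the mean core permeability and the inductance split
L_total = L_p + L_s.  The mean permeability collapses as the core
saturates, while the loose-coupling geometry keeps the total inductance
change modest.
"""

import numpy as np

import coilcore as cc
from coilcore.nonlinear import BemWorkspace
from coilcore.runner import build_coil, build_core

cfg = cc.make_fixture("loop_cylinder", resolution="coarse", I0=1.0,
                      material={"preset": 2})
coil = build_coil(cfg.coil, 1.0)
mesh = build_core(cfg.core)
ws = BemWorkspace(mesh, None, coil)
curve = cc.preset_material(2)
print(f"core: {mesh.n_tets} tets, {ws.faces.n_faces} faces "
      f"(boundary + inner); coil: {coil.n_segments} filaments")
print(f"material #2 (M3 silicon steel fit): mu_r0 = "
      f"{cc.initial_permeability(curve):,.0f}")

print(f"\n{'I0 (A)':>10} {'mean mu_r':>10} {'L_p (nH)':>9} "
      f"{'L_s (nH)':>9} {'L_total (nH)':>12} {'sweeps':>6}")
for I0 in (1e-3, 100.0, 20e3):
    wsI = ws.with_current(I0)
    sol, log = cc.solve_nonlinear_core(mesh, curve, wsI.coil, workspace=wsI)
    ind = sol.core_energy_and_inductance()
    print(f"{I0:>10g} {sol.mu_r.mean():>10.1f} {ind['L_p']*1e9:>9.2f} "
          f"{ind['L_s']*1e9:>9.2f} {ind['L_total']*1e9:>12.2f} "
          f"{len(log.e1):>6d}")

print("\nmean mu_r drops by orders of magnitude in saturation while the")
print("loosely coupled loop keeps most of its free-space inductance.")
print("(at this coarse demo resolution the few-percent L_s differences")
print("are at the discretization level; the finer 'default' fixture")
print("resolves the saturated drop in L_s clearly.)")
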