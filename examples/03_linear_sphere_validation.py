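"""Linear-core solve against the magnetizable-sphere closed form.

A mu_r = 3 sphere in the nearly uniform field of a large loop pair acquires
the uniform magnetization |M| = 3 (mu_r - 1)/(mu_r + 2) |H0|, and its
exterior secondary field is that of a point dipole with moment
(4 pi a^3 / 3) M.  Both are reproduced here by the surface-charge solver.
"""

import numpy as np

import coilcore as cc

coil = (cc.circular_loop(0.5, n_segments=128, center=(0, 0, -0.25), I0=100.0)
        + cc.circular_loop(0.5, n_segments=128, center=(0, 0, 0.25), I0=100.0))
H0 = cc.primary_B(coil, [[0, 0, 0]])[0] / cc.MU0
print(f"applied field |H0| = {np.linalg.norm(H0):.2f} A/m")

a, mu_r = 0.025, 3.0
mesh = cc.sphere_mesh(a, 14)
sol = cc.solve_linear_core(mesh, mu_r, coil)
print(f"sphere: radius {a*1e3:.0f} mm, {mesh.n_tets} tets, "
      f"{sol.faces.n_faces} boundary faces, "
      f"GMRES iterations {sol.solve_info['iterations']}")

Mmag = np.linalg.norm(sol.M, axis=1).mean()
expect = 3 * (mu_r - 1) / (mu_r + 2) * np.linalg.norm(H0)
print(f"|M| inside        = {Mmag:.2f} A/m (closed form {expect:.2f} A/m)")

p = np.array([[3 * a, 0, 0]])
Hs = sol.secondary_H_outside(p)[0]
m = (4 * np.pi * a**3 / 3) * expect * np.array([0, 0, 1])
r = np.linalg.norm(p[0]); rh = p[0] / r
Hd = (3 * rh * np.dot(rh, m) - m) / (4 * np.pi * r**3)
print(f"exterior H_s at 3a on the equator = {Hs[2]:.4f} A/m "
      f"(dipole closed form {Hd[2]:.4f} A/m)")

ind = sol.core_energy_and_inductance()
print(f"core energy U_s = {ind['U_s']:.3e} J, "
      f"inductance correction L_s = {ind['L_s']*1e9:.3f} nH")
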