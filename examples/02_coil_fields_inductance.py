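"""Filament coils: Biot-Savart fields and Neumann-formula inductance.

Builds a 10 mm one-turn loop of 1 mm wire as a filament bundle, checks the
textbook center field, and compares the Neumann double-sum inductance with
the uniform-current thick-wire formula mu0*R*(ln(8R/a) - 1.75).
"""

import numpy as np

import coilcore as cc

R, a, I0 = 0.01, 0.001, 10.0
loop = cc.circular_loop(R, a, n_segments=256, n_filaments=25, I0=I0)
print(f"loop: R = {R*1e3:.0f} mm, wire radius = {a*1e3:.0f} mm, "
      f"{loop.n_segments} segments in {loop.n_parallel} filaments")

B = cc.primary_B(loop, [[0, 0, 0]])[0]
print(f"B at center       = {np.linalg.norm(B)*1e3:.4f} mT "
      f"(closed form {cc.MU0*I0/(2*R)*1e3:.4f} mT)")

L = cc.self_inductance(loop)
L_formula = cc.MU0 * R * (np.log(8 * R / a) - 1.75)
print(f"self-inductance   = {L*1e9:.2f} nH "
      f"(thick-wire formula {L_formula*1e9:.2f} nH)")

other = cc.circular_loop(R, n_segments=256, center=(0, 0, 0.1))
M = cc.mutual_inductance(loop, other)
M_dip = cc.MU0 * np.pi * R**4 / (2 * 0.1**3)
print(f"mutual inductance to a coaxial loop 100 mm away = {M*1e12:.3f} pH "
      f"(dipole limit {M_dip*1e12:.3f} pH)")

# Litz bundle sizing: 100 strands of 0.15 mm radius
rb = cc.litz_bundle_radius(0.15e-3, 100)
print(f"optimal 100-strand Litz bundle radius = {rb*1e3:.3f} mm")

E = cc.primary_E(loop, [[0.004, 0, 0.006]], dIdt=1e8)[0]
print(f"induced E at (4,0,6) mm for dI/dt = 100 A/us: "
      f"|E| = {np.linalg.norm(E):.2f} V/m")
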