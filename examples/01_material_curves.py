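"""Anhysteretic B-H curves: the three preset core materials.

Prints the small-signal permeability, the saturation ceiling of B - mu0*H,
and the maximum permeability variation rate for each preset.  The variation
rate controls how hard the nonlinear solve is: materials with hundreds of
uH/A need far more care than the generic ~0.1 uH/A curve.
"""

import numpy as np

import coilcore as cc

for mid in (1, 2, 3):
    curve = cc.preset_material(mid)
    print(f"material #{mid}: {curve.kind}, a1 = {curve.a1:.4g}, "
          f"a2 = {curve.a2:.4g}")
    print(f"  small-signal mu_r0              = "
          f"{cc.initial_permeability(curve):,.0f}")
    print(f"  saturation of B - mu0*H         = "
          f"{cc.saturation_flux_excess(curve):.3g} T")
    print(f"  max |d(mu0 mu_r)/dH|            = "
          f"{cc.max_permeability_rate(curve) * 1e6:.3g} uH/A")
    H = np.array([1e2, 1e3, 1e4, 1e5])
    B = cc.flux_density(curve, H)
    print("  B(H) at 0.1/1/10/100 kA/m       =",
          " ".join(f"{b:.3f} T" for b in B))

# round-trip: fit the Froelich model to sampled locus points
truth = cc.preset_material(2)
H = np.logspace(2, 5, 8)
fit = cc.fit_curve(np.column_stack([H, cc.flux_density(truth, H)]),
                   "froelich")
print(f"\nfit to sampled loci of material #2: a1 = {fit.a1:.4f} "
      f"(true 40), a2 = {fit.a2:.4f} (true 0.50)")
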