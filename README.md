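# coilcore

Charge-based boundary-element magnetostatics for transcranial magnetic
stimulation (TMS) coils with linear and **nonlinear magnetic cores**.

TMS coils with soft-magnetic cores can focus the stimulating field and cut
drive energy, but their modeling is awkward: commercial magnetostatic FEM
packages do not output the induced electric field that TMS dosimetry needs,
and most open TMS toolchains ignore cores entirely.  `coilcore` solves the
coil + core problem once, up front, and then evaluates every quantity of
interest — core magnetization **M**, coil inductance with and without the
core, and the induced electric field **E** — from the stored solution, for
any pulse rate dI/dt and any rigid placement of the assembly.

## Model

* **Coil.**  The windings are a cloud of short straight filaments; segment
  *m* carries the current fraction `w_m` of the terminal current `I0`
  (a Litz conductor is a bundle of equally weighted parallel filaments).
  Free-space fields follow from Biot–Savart sums,

  `A_p(r) = mu0/4pi * sum_m I0 w_m s_m / |r - r_m|`,
  `B_p = curl A_p`,  `E_p = -(dI/dt) A_p / I0`,

  and the no-core inductance from the Neumann double sum
  `L_p = mu0/4pi * sum_m |w_m s_m . sum_{n != m} w_n s_n / |r_m - r_n||`.

* **Core.**  The core is a tetrahedral mesh with a constant permeability
  per tet.  Its effect is represented by a fictitious magnetic surface
  charge density `rho` (tesla) impressed on **every** face of the mesh —
  boundary *and* inner — so that the normal flux density is continuous
  across each face.  Continuity yields a Fredholm equation of the second
  kind,

  `rho/2 - K n . (1/4pi) int (r - r')/|r - r'|^3 rho dS' = K n . B_p`,

  with the per-face contrast `K = (mu+ - mu-)/(mu+ + mu-)` (`mu- = mu0` on
  the boundary), solved matrix-free by GMRES with closed-form near-field
  panel integrals.

* **Nonlinearity.**  Saturation enters through an anhysteretic B–H curve,
  either `mu0 mu_r = a1 atan(a2 H)/H + mu0` (arctan) or
  `mu0 mu_r = 1/(a1 + a2 H) + mu0` (Froelich).  Successive substitution
  alternates the charge solve with a pointwise permeability update
  `mu(|H_p + H_s|)` per tet until the relative changes of the charges (e1)
  and permeabilities (e2) are small.  Optional aids for stiff cases:
  neighbor smoothing of `mu` (weight `alpha`) and a face-averaged secondary
  field blend (weight `beta`).

* **Outputs.**  `M = (mu_r - 1) H` per tet; the core energy
  `U_s = 1/2 int M . B_p dV` gives the inductance correction
  `L_s = 2 U_s / I0^2`; the total induced field is
  `E = -(dI/dt)(A_p + A_s)/I0` with `A_s` the dipole sum over magnetized
  tets.

## Worked example

A mu_r = 3 sphere (radius 25 mm) in the nearly uniform field of a large
loop pair has the classical uniform magnetization
`|M| = 3 (mu_r - 1)/(mu_r + 2) |H0|` and a pure dipole exterior field:

```sh
$ python examples/03_linear_sphere_validation.py
applied field |H0| = 143.15 A/m
sphere: radius 25 mm, 16464 tets, 2352 boundary faces, GMRES iterations 5
|M| inside        = 174.13 A/m (closed form 171.79 A/m)
exterior H_s at 3a on the equator = -2.0660 A/m (dipole closed form -2.1208 A/m)
core energy U_s = 1.019e-06 J, inductance correction L_s = 0.204 nH
```

The solver reproduces the closed-form magnetization to ~1% at this mesh
resolution and the exterior dipole field to ~2.5% (both converge under
refinement).  The other scripts in `examples/` cover the material models
(`01`), coil fields and inductances (`02`), the nonlinear saturation sweep
on a one-turn loop + cylinder core (`04`), and the multi-winding rodent-
coil-style assembly (`05`).

A thin CLI wraps the same library:

```sh
coilcore material-info --preset 2
coilcore fixtures loop_cylinder --out run.yaml --current 20000
coilcore solve --config run.yaml
```

## Layout

```
src/coilcore/
  materials.py   B-H curve models, presets, fitting, diagnostics
  coil.py        filament coils, Biot-Savart fields, Neumann inductance
  core_mesh.py   tet primitives, STL import, face topology, VTK output
  bem_linear.py  surface-charge operator, GMRES solve, linear-core pipeline
  nonlinear.py   successive substitution over all mesh faces
  fields.py      magnetization, energy/inductance, A_s, E, rigid motion
  runner.py      run configs, fixtures, reports
  cli.py         command-line interface
docs/methods.md  modeling assumptions, numerics, limitations
```
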