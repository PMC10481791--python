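# Methods

This note records the modeling assumptions, the numerical choices, and the
limits of what the test suite demonstrates.  SI units are used throughout
(meters, amperes, tesla, henry); the magnetic surface charge density
carries tesla (Wb/m^2).

## Physical model and assumptions

The solver works in the magnetoquasistatic approximation: the coil current
separates as `j(r, t) = I(t) j(r)`, displacement currents are neglected,
and the induced electric field is `E = -(dI/dt) A / I0` with `A` the total
magnetic vector potential at terminal current `I0`.  The core is assumed
non-conducting (no eddy currents inside the core) and isotropic, and the
coil current distribution is taken as unaffected by the core.

The primary (free-space) coil fields come from midpoint-rule Biot–Savart
sums over straight filaments.  A finite conductor cross-section is modeled
as a bundle of parallel, equally weighted filaments — the uniform-current
Litz-wire model; skin-effect redistribution in solid conductors is out of
scope.

The core's response is represented by fictitious magnetic surface charge.
For a *linear* core only the boundary carries charge and the classical
second-kind Fredholm equation applies.  For a *nonlinear* core the
tetrahedral volume mesh carries a constant permeability per tet, and the
same integral equation is applied to **all** faces of the mesh (inner and
boundary) with the differential contrast `K = (mu+ - mu-)/(mu+ + mu-)`
taken between the two adjacent tets (vacuum on the outside of boundary
faces).  Each face has a plus/minus orientation chosen as "plus = lower tet
index"; the choice is arbitrary and the tests confirm the solution is
invariant under relabeling.

Saturation is described by a single-valued anhysteretic B–H curve:
hysteresis, coercivity, and loss models (hysteresis/eddy/anomalous) are
deliberately excluded, which is adequate for magnetically soft TMS core
materials and high-flux operation.  Both curve families include the
additive `mu0` term so that `mu_r -> 1` in deep saturation; this vacuum
floor matters at TMS-level flux densities.

## Nonlinear iteration

Successive substitution: (1) secondary field `H_s` at tet centroids from
the current charges; (2) permeability update `mu(|H_p + H_s|)` from the
curve, optionally smoothed over face-neighbor tets with weight `alpha`
(`mu <- alpha mu + (1-alpha)/4 sum(neighbors)`, missing neighbors of
boundary tets retain their weight on the tet itself); (3) per-face
contrasts; (4) GMRES re-solve of the charge equation, warm-started from
the previous charges.  Convergence is declared when both relative
deviations `e1 = |rho_n - rho_{n-1}|/|rho_n|` and
`e2 = |mu_n - mu_{n-1}|/|mu_n|` (Euclidean norms) fall below their
tolerances; defaults are `tol_e1 = 1e-3`, `tol_e2 = 5e-3`, at most 30
sweeps.

Newton–Raphson linearization is deliberately not implemented; fixed-point
substitution with the stabilizers below covers the anhysteretic curve
families targeted here.

The method's stability is governed by the material's maximum permeability
variation rate `max |d(mu0 mu_r)/d|H||`: ~0.1 uH/A for the generic arctan
material versus ~310 and ~130 uH/A for the two Froelich fits.  For stiff
cases a *face-averaging stabilizer* with weight `beta` replaces a fraction
of the centroid secondary field by the average of the four just-inside
face-center values, reconstructed from the principal value plus the charge
jump `rho/(2 mu0)` across each face.  `beta = 0` by default;
on detected divergence (e1 and e2 rising for five consecutive sweeps) the
solver restarts itself once with `beta = 0.25`.  The defaults
`alpha = 0.4`, `beta = 0` are package choices: at ~10^4 faces the steep
Froelich curves develop a slowly growing fine-scale mode for alpha above
~0.6 that the stronger neighbor smoothing suppresses, while the converged
mean permeability shifts by only ~2% between alpha 0.4 and 0.7 on the
benchmark fixtures; the stabilizer is kept off until needed because it
slightly smears interior fields.  The tolerances mirror the converged
deviations the method typically reaches.

At convergence the reported permeability and magnetization are evaluated
from the *raw* curve at the converged field, not from the smoothed
iterate: smoothing is an iteration aid, and reported `|M|` must respect
the constitutive ceiling `(B - mu0 H) <= a1 pi/2` (arctan) or `1/a2`
(Froelich).

## Discretization and numerics

* **Panel integrals.**  The field of a constant-density triangle is
  evaluated in closed form (signed solid angle for the normal part,
  per-edge line potentials for the in-plane part); the principal value on
  the face itself falls out as the in-plane part alone.  Exact integrals
  are used between a face and its vertex-sharing neighbors (and from a
  face to any tet centroid of a vertex-sharing tet); all farther
  interactions use a one-point centroid rule.  Point-based evaluators
  switch to exact integrals within three face sizes of a face.
* **Linear algebra.**  The charge equation is solved by GMRES (relative
  tolerance 1e-8, up to 300 inner iterations).  The normal-field operator
  is available matrix-free (blocked direct summation plus a sparse
  near-field correction) and as an explicitly assembled dense matrix; the
  dense form is cached for meshes up to ~16k faces because the nonlinear
  loop re-applies it many times.  Face-to-tet-centroid influence matrices
  are precomputed in float32 (their rounding, ~1e-7 relative, is far below
  the quadrature error).  No FMM backend is provided; all summations are
  blocked direct evaluation.
* **High-contrast interior fields.**  For `mu_r > 1e3` the interior field
  obtained as `H_p + H_s` suffers catastrophic cancellation (the interior
  field is ~`mu0/mu` of the applied one).  The linear solver then rebuilds
  the normal component at boundary tets from the flux jump condition
  `n.H_in = (mu0/mu) n.H_out`.  Weak-field consistency between the
  nonlinear pipeline and the small-signal linear solve is therefore
  asserted on the charge density (well-conditioned), not on interior
  fields.
* **Meshes.**  Structured primitives use the Kuhn 6-tet decomposition of
  hex cells (conforming across cells); cylinder prisms are split through
  their centroid with quad diagonals chosen by the minimum-global-vertex-
  index rule (conforming by construction).  STL import tetrahedralizes the
  interior by Delaunay over the surface vertices plus a jittered interior
  lattice, with inside/outside decided by generalized winding number;
  external TetGen-style node/ele meshes are read as-is.  Unit convention:
  meshes are meters; STL import takes an explicit scale (default mm -> m
  in run configs).
* **Determinism.**  The pipeline has no random component; the only RNG
  (interior-lattice jitter in STL import) is fixed-seeded.  Repeated runs
  reproduce reports bit-identically.

## Validation fixtures — what they do and do not show

* `sphere_uniform`: a mu_r = 3 sphere in a large loop pair (applied-field
  nonuniformity < 1% across the sphere).  Checks the classical uniform
  magnetization `|M| = 3(mu_r-1)/(mu_r+2) |H0|` (within 2%) and the
  exterior dipole field (within 2% at r >= 2a) at ~5k boundary faces.
  The pointwise identity `rho = mu0 n.M` converges only at first order in
  the mesh size — flat facets tilt the local normals — so it is asserted
  at the few-percent level with a refinement-monotonicity check rather
  than at a fixed small tolerance.
* `loop_cylinder`: a solid cylinder (radius 10 mm, height 40 mm) centered
  in a loose one-turn Litz loop (radius 25 mm, conductor radius 2 mm).
  At 20 kA every preset material saturates deeply (|H| ~ 1e5 A/m in the
  core).  The suite asserts the saturation *patterns*: mean core mu_r
  decreases monotonically over a 1 mA / 100 A / 20 kA sweep, and the total
  inductance of the saturated core lies strictly between the no-core and
  small-signal linear-core values.  Problem sizes: ~5.5k tets / ~11k faces
  for the acceptance-level runs, ~500 tets for unit tests; these sizes are
  the package's chosen validation scale and converge in a few dozen
  sweeps.
* `rat_coil_like`: two 20-turn skewed (15 degrees) helical spirals of
  radii 9 and 16 mm, 110 mm total length, optional 6-turn booster, square
  magnetic bar.  The true device's pitch profile and core cross-section
  are not public; the fixture documents its own linear pitch taper
  (7.5 -> 3.5 mm) and 8 x 8 mm^2 bar and is used for topology and pattern
  checks, not for reproducing specific measured inductances.

The synthetic fixtures exercise smooth, convex or mildly non-convex cores
and idealized drive currents.  They do not probe sharp-edged cores at
extreme permeability (where charge density is singular along edges),
laminated anisotropic stacks, conducting cores, or measured B–H data with
low-field permeability peaks (the arctan/Froelich fits deliberately ignore
the sub-300 A/m peak of silicon-steel datasheets).  Passing tests
therefore demonstrate correctness of the implemented model, not fidelity
of these simplifications for any particular hardware.

## Known limitations

* First-order (flat-facet, centroid-collocation) BEM accuracy: closed-form
  sphere quantities converge as O(h); a few percent at ~10^4 tets.
* The all-faces formulation stores charge on interior faces whose contrast
  is nonzero only through permeability gradients; very steep B-H curves
  (hundreds of uH/A variation rate) can stall near e1 ~ 1e-3 at fine
  resolution unless the face-averaging stabilizer is engaged.
* Inductance of a single infinitely thin filament loop is log-divergent as
  segments refine (the Neumann diagonal is dropped); the package warns and
  expects a filled conductor cross-section.
* The deformed-primitive generator supports affine maps only.
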