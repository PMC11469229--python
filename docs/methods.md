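# Methods note

`marrowmech` models how a mechanical disturbance applied to a blood vessel
embedded in deep bone marrow propagates along and through the vessel wall
and the surrounding tissue. It covers three vessel classes — arteriole,
artery, and sinusoid — with quasi-static inflation/bending analyses and
explicit transient wave-propagation analyses on synthetic tubular
geometries, followed by surface stress statistics.

## Unit system

All internal quantities use a consistent **µm–µs–MPa** system:

| quantity | unit | note |
|---|---|---|
| length | µm | |
| time | µs | |
| stress, moduli, pressure | MPa | reported stresses converted to kPa |
| density | 10⁶ kg/m³ | water = 1.00 × 10⁻³ |
| velocity | µm/µs | numerically equal to m/s |
| pressure input | mmHg | 1 mmHg = 1.333224 × 10⁻⁴ MPa |

With these units an elastic wave speed √(E/ρ) comes out directly in m/s,
and time steps for micrometre-scale meshes are O(10⁻³) µs.

## Geometry

`make_tube_mesh` builds structured tetrahedral tubes from concentric node
rings (no interior axis node). Defaults are the study conditions:

| class | length (µm) | lumen radius (µm) | wall (µm) | regions |
|---|---|---|---|---|
| arteriole | 200 | 15 | 5 | blood, wall |
| artery | 200 | 15 | 14.3 | blood, wall |
| sinusoid | 300 | 20 | ≈ 0 (ignored) | blood, marrow |

The blood region fills the lumen as a hollow-core annulus whose innermost
node ring sits at half a radial spacing from the axis; the resulting void
is ≈ 1 % of the lumen volume, negligible for mass. The sinusoid wall is
modelled as a material-free interface (its thickness is negligible), so a
sinusoid mesh is blood surrounded directly by marrow out to a documented
synthetic outer radius of 100 µm (about five lumen radii, far enough that
the outer boundary does not dominate the wave field over the simulated
windows). Surface sets (`end_A`, `end_B`, `outer_wall` or `marrow_outer`,
`inner_lumen`, `lumen_core`) are derived from lattice indices, cover the
boundary exactly once, and are outward-oriented.

Helpers exist for emulating reconstructed-microscopy geometry: surface
extraction, Taubin smoothing, inward offsetting (with inversion/self-
intersection detection), and seeded sinusoidal perturbation of the wall to
mimic irregular vessel cross-sections.

## Materials

| region | model | parameters | density (10⁶ kg/m³) |
|---|---|---|---|
| vessel wall | 5-parameter Mooney–Rivlin | C10 = 0.115, C01 = −0.049, C20 = 1.403, C11 = −3.370, C02 = 2.201 MPa | 1.10 × 10⁻³ |
| marrow | linear elastic | E = 0.01 MPa, ν = 0.45 | 1.00 × 10⁻³ |
| blood | linear elastic ("mass only") | E = 10⁻⁴ MPa, ν = 0.3 | 1.06 × 10⁻³ |

The wall strain energy uses isochoric invariants plus a volumetric penalty
U_vol = (1/D1)(J−1)² with D1 chosen so that κ/µ₀ = 1000
(µ₀ = 2(C10+C01) = 0.132 MPa) — effectively incompressible. Defaults
filled where the source tables are silent (and overridable): marrow
ν = 0.45 (soft-tissue range), blood given a vanishing stiffness so its
elements stay non-singular while contributing only inertia. First
Piola–Kirchhoff stress is analytic; the material tangent is obtained by
finite differences of the stress (h = 10⁻⁶), verified against the energy
to 10⁻¹¹ in tests.

## Quasi-static solver

Total-Lagrangian displacement formulation on linear tetrahedra with full
Newton iteration and incremental load stepping. Near-incompressibility
(marrow ν = 0.45, wall κ/µ = 1000) is handled with an average-nodal-
pressure projection (mean-dilatation family): the volumetric energy is
evaluated on nodal volume averages, giving an exact energy/force/Hessian
triple, so Newton stays quadratic and the explicit energy ledger closes.
Luminal pressure is a follower load recomputed on the deformed surface;
its geometric stiffness is omitted from the tangent (the residual remains
exact; a few extra iterations are the only cost). Bending is applied by
prescribing a transverse displacement d on the midspan node ring with both
ends clamped.

Verified against the Lamé thick-walled-cylinder solution (ring-binned hoop
stress and radial displacement within ~3 % at 3 µm resolution), a patch
test (uniform stress to 10⁻⁸ under affine boundary displacement), and
pressure linearity in the small-strain regime.

## Explicit dynamics

Central-difference integration with a lumped (row-sum) mass matrix. The
stable step is the CFL bound `safety · min(h_e / c_e)` with the
dilatational speed c = √((κ + 4µ/3)/ρ) per element; default safety 0.5.
The vibratory end pulse displaces one end ring by a half-cosine ramp
(default 1 µm in 1 µs) **transverse to the vessel axis**; an axial variant
(`pulse_direction="z"`) exists for rod-wave benchmarks. An energy ledger
(external work of reactions and pressure by trapezoidal quadrature,
kinetic energy from staggered velocities, strain energy from the model)
is recorded at every snapshot; measured drift is ~10⁻⁶ relative over 5 µs.
Element inversion or kinetic-energy blow-up aborts with a stability error.
`couple_prestress` first equilibrates the luminal pressure quasi-
statically (both ends clamped), then starts the transient from that state;
at zero pressure the path is bit-identical to a cold start.

The transverse pulse matters physically: with luminal prestress, a
transverse excitation rides on top of tensile hoop/axial stress and the
peak surface von Mises increases monotonically with pressure (measured
20.6 / 23.3 / 26.4 kPa at 0 / 50 / 100 mmHg on the default artery tube at
t = 1 µs). An axial pulse instead cancels deviatorically against the
prestress and would show the opposite trend.

## Postprocessing

Outer-surface element von Mises stress is unwrapped onto a cylindrical
(z, arc-length) grid of 10 µm cells (area-weighted facet averages, kPa).
The cell-value histogram (1 kPa bins) is fitted with a Gaussian; when the
sample range spans fewer than six bins the bin width auto-refines to
range/12, since a near-degenerate histogram cannot constrain a
3-parameter fit — a scale-free robustness rule, not a tuned constant.
Reported statistics: fitted mode and width, maximum surface stress
σ_Smax, and the area fraction of cells at or above a 10 kPa threshold.
The stress-front tracker follows the location of the surface stress
maximum across snapshots and reports mean and interval velocities.

## Numerical and scope choices

- Structured tubes stand in for confocal-reconstructed geometry; absolute
  front velocities and stress maxima are therefore geometry-dependent,
  and the package asserts orderings and ratios rather than absolute
  field values (the bending kinematics are geometry-independent and are
  asserted exactly).
- The pressure-linearity check on the artery tube is run at an 8 µm mesh
  in the test suite (the 3 µm result was verified once during
  development; 8 µm reproduces the mode ratio within tolerance at ~100×
  lower cost and is the documented coarser fallback).
- Linear tetrahedra carry constant stress per element; oracle
  comparisons therefore bin element-centroid values and compare against
  the exact solution averaged at the same centroids.
- No damping, contact, fluid dynamics, or bone beam-theory stress
  recovery; the bending module treats the vessel displacement as equal
  to the bone displacement.

## Bending kinematics

A vessel of length L bonded to bone bent to a circular arc at bending
strain ε = ΔL/L satisfies θ/sin θ = 1 + ε for the half-arc angle θ
(solved by bracketed bisection to 10⁻¹⁰). The bending radius is
r = L(1+ε)/(2θ) and the midspan transverse displacement is the sagitta
d = (L/2)(1+ε)·tan(θ/2) (a chord-referenced variant without the (1+ε)
factor, 0.1–0.3 % smaller, is available by flag). For L = 200 µm this
gives d = 3.88 µm at ε = 0.001 and d = 5.49 µm at ε = 0.002 (two
decimals).
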