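# Methods

## The physical problem

A flagellotropic bacteriophage attaches to a bacterial flagellum by a
helical tail fibre and is carried along the rotating filament like a nut on
a bolt: the chirality of the fibre helix couples the flagellum's rotation
to an axial translocation of the phage.  At these scales (tens of
nanometres, ~100 Hz) the Reynolds number is ~1e-9, so the water around the
complex obeys the steady incompressible Stokes equations,

    div v = 0,        grad p = mu * laplacian v,

with no-slip conditions on every solid surface and rest conditions far
away.  The package computes the steady translocation speed `U` of the phage
for two mechanical models of the complex and compares the full
hydrodynamics with a resistive-force-theory (RFT) twin.

**Model 1 (smooth flagellum).**  The flagellum is a cylinder of radius
`R_fl` along z.  The fibre centreline is the helix

    r(l) = [ Rh cos(l sin a / Rh), h Rh sin(l sin a / Rh), z0 + l cos a ],
    Rh = R_fl + d,   0 <= l <= L_fib,

with helix angle `a`, chirality `h = +/-1` and standoff `d = 2 r_fib`.
The phage has three degrees of freedom: its rotation rate about the
flagellum axis `w_p` and translocation speed `U`, driven by the flagellum
rotation `w_fl = 2 pi f`.

**Model 2 (grooved flagellum).**  The flagellum carries a helical groove
replicating the fibre (swept circular channel of radius `r_fib + h_gap`,
concentric with the fibre helix, which now lies at radius
`R_fl + r_fib cos(pi f_cov)` so a fraction `f_cov` of the fibre
circumference sits below the nominal surface).  The fibre is guided by the
groove: its absolute velocity is a screw motion along the groove helix with
magnitude `V`, and a restoring force per unit length `k*delta` along the
local Frenet binormal keeps it in the groove.  The unknowns are
`(k*delta, V)` with `U = V cos a`.

**Linearised mobility problem.**  Loads are linear in the kinematic rates,
so unit "elementary motions" (one degree of freedom at a time) define the
coefficients `C1..C6` (axial force and torque on the phage per unit rate).
The steady state nulls the net axial force and torque on the phage:

    model 1:  C1 w_fl + C2 w_p + C3 U = 0,   C4 w_fl + C5 w_p + C6 U = 0
    model 2:  C1 w_fl + h L_fib (k d) sin a + C3 V = 0,
              C4 w_fl -   L_fib R_fl (k d) cos a + C6 V = 0.

In the model-2 torque row the chirality factor cancels: the restoring
force is `k*delta` times the Frenet binormal, whose z-component carries `h`
while its azimuthal component does not.  Writing `h` in both rows (as some
presentations do) breaks the required antisymmetry `U(-h) = -U(h)`; both
conventions agree at `h = +1`.  As tail drag dominates, model 2 approaches
the rigid-riding limit `U = w_fl R_fl cot a` (the axial velocity of a
material point of the rotating groove helix).

## Baseline parameters

| parameter | value | meaning |
|---|---|---|
| `R_fl` | 10 nm | flagellum radius |
| `L_fl` | 124 nm (alternative 248) | flagellum segment length |
| `a_h` | 30 nm | head radius |
| `L_t`, `r_tail` | 220 nm, 7 nm | tail cylinder |
| `L_fib`, `r_fib` | 200 nm, 1 nm | fibre contour length and radius |
| `alpha` | 51 deg | helix angle |
| `tail_tilt` | 45 deg | tail axis angle to the flagellum axis |
| `d` | `2 r_fib` | model-1 centreline standoff |
| `h_gap` | `r_fib / 2` | model-2 groove bottom clearance |
| `f_cov` | 0.5 | fibre circumference fraction in the groove |
| `f` | 100 Hz | flagellum rotation frequency |
| `mu` | 1e-3 Pa s | water viscosity |

Internal unit system: lengths in nm, time in s, viscosity in Pa s; forces
then carry the consistent unit `Pa s nm^2/s`, which cancels in every
mobility solve and friction-coefficient ratio.  The velocity scale
`w_fl R_fl` is 6.28 um/s and the rigid-riding limit at the baseline is
5.09 um/s.

The fibre start `z0` centres the fibre axially on the flagellum segment
(the open flagellum ends are hydrodynamically inert, which is why two
segment lengths are supported).  The tail is attached at the fibre's upper
end, tilted 45 deg in the plane of the local radial direction and z, with a
clearance gap (default `r_fib`) to both fibre and flagellum; the head
sphere is tangent to the tail's far cap.

## Numerical method

**Meshing.**  Bodies are represented by signed-distance functions
(positive in the fluid).  Points are placed on every body surface and
through the volume with a graded size field (0.75 nm at the fibre, 2.5 nm
at tail and head, 25 nm in a sphere around the complex, 50 nm beyond, all
times a global `scale`; growth away from refined bodies is limited to 0.3
per unit distance, i.e. a ~1.3 per-cell gradation at every scale).
Surface spacing is additionally capped by per-body resolvability limits
(e.g. 1.3 `r_fib` on the fibre tube) so coarse scales stay geometrically
meaningful.  The cloud is Delaunay-tetrahedralised (scipy/Qhull);
tetrahedra whose centroid lies inside a body or outside the outer sphere
are discarded; boundary facets inherit the adjacent body's tag.  Two
Lloyd-style smoothing passes improve interior quality.  This point-based
mesher produces some boundary slivers (dihedral angles down to ~0.5 deg);
the quality floor is therefore configured at 0.2 deg and accuracy is
validated by the sphere oracles rather than by angle bounds.

Ten-node (P2) elements are formed by edge-midpoint insertion; midpoints of
boundary edges are projected onto the analytic surfaces, giving curved
isoparametric elements (any element inverted by projection is straightened
back).  Midside nodes of edges that bridge two *different* bodies across an
under-resolved clearance remain free, and a helical sheet of free interior
points is seeded at mid-gap between the fibre and the wall (standoff gap in
model 1, groove clearance in model 2).  Without these two measures the
narrow-gap elements would have every node Dirichlet-constrained to
incompatible wall data and the penalty term would manufacture O(lambda)
spurious loads; with them, one element layer resolves the gap shear.

**Penalty Stokes solver.**  Velocity uses second-order elements; the
discrete problem minimises

    J(v) = int [ 2 mu eps(v):eps(v) + lambda (div v)^2 ] dV,

which is the standard viscous dissipation (for a pure shear `u = gamma y`,
J = mu gamma^2 V).  The viscous term is integrated with a degree-5
conical-product rule (positive weights, exact for straight P2 elements);
the penalty term is under-integrated at the element centroid.  The
centroid rule makes the recovered pressure `p = -lambda div v` piecewise
constant - the inf-sup-stable P2/P0 pair; richer reduced rules
(discontinuous-P1 pressure) were found to carry spurious pressure modes on
tetrahedra that swamp the physics.  `lambda = 1e7 mu` by default, chosen
where the divergence norm (which scales as 1/lambda) is far below the
strain scale while the factorisation stays well conditioned.  The
assembled SPD system is factorised once per mesh with symmetric-mode
sparse LU (SuperLU, minimum-degree ordering, no partial pivoting); every
elementary motion then costs one back-substitution.

**Loads.**  Forces and torques on a body use the variationally consistent
(residual) route: the nodal reactions `R = K u` on the body's Dirichlet
nodes give `F = -sum R` and `M_z = -sum (x R_y - y R_x)` - the
superconvergent boundary-flux evaluation.  A direct route (element-stress
tractions `t = sigma . m` on the curved boundary faces) is provided as an
independent cross-check and for VTU export; it is one order less accurate
and agrees with the variational route within ~10 % on the sphere fixture.
Discrete Lorentz reciprocity (C2 = C6 in model 1) holds to solver
precision by construction of the residual route, and is asserted.

**Friction-coefficient extraction.**  The RFT fibre drag integral with
unknown `zeta_perp` (and `zeta_par = zeta_perp/2`) is matched to the FEM
force and torque on the fibre surface for one elementary motion by
relative least squares.  The "translocation route" uses the phage
translation motion (C3/C6 data), the "rotation route" the flagellum
rotation motion (C1/C4 data).

## The RFT twin

Each phage element feels a local anisotropic drag: the fibre uses the
near-wall slender-body coefficients

    zeta_perp = 4 pi mu / ln(2 d / r_fib),     zeta_par = zeta_perp / 2,

evaluated on the velocity *relative to the nearest flagellum-surface
material point* (the coefficient models the wall interaction; without the
relative velocity the flagellum-rotation coefficients C1/C4 would vanish
identically in a local theory).  The tail uses free-space slender-body
values `4 pi mu/(ln(2L/r)+1/2)` and `2 pi mu/(ln(2L/r)-1/2)`; the head uses
Stokes sphere drag `6 pi mu a` and spin torque `8 pi mu a^3`.  In model 2
the immersed arc of the fibre is resisted by a Couette sliding law
`zeta_groove = mu (f_cov 2 pi r_fib)/h_gap` per unit length and the exposed
arc keeps the near-wall law weighted by `1 - f_cov`.  At the baseline,
`zeta_perp = 0.00906 Pa s` and `zeta_groove = 2 pi mu`.

## Study conditions used by the test suite

FEM runs in the test suite use a desk-scale configuration chosen once:
fibre contour length 80 nm (the full 200 nm geometry is retained as the
package default and in all RFT evaluations), mesh scale 6 with the
resolvability caps active, outer boundary at 2.2 x the circumscribed
radius, fixed meshing seed.  A case at these conditions has ~18-28 k
elements (~80-120 k velocity unknowns) and factorises in about a minute on
one CPU.  At these conditions:

* sphere drag and torque match the container-corrected closed forms within
  ~1-3 % (the no-slip container at 20 sphere radii raises drag by 10.5 %,
  so the unbounded formula alone is not the right oracle);
* the extracted fibre friction coefficients are ~0.0078 (translocation
  route) and ~0.0068 (rotation route) against the converged-mesh reference
  values 0.00763 and 0.00663, with the ordering (rotation < translocation
  < analytic 0.00906) reproduced strictly;
* all trend directions (tail length down/up for models 1/2, approach to
  the rigid-riding limit from below, head size up, groove coverage down)
  agree between FEM and the RFT twin.

Magnitude checks at desk scale therefore carry relaxed bands (25 % on the
extracted friction coefficients, 10 % on the limit proximity at the
largest tail, a 2-55 % window on the model-1 FEM-below-RFT gap, ratio >= 2
on the model-2/model-1 speed comparison), while orderings, sign laws,
reciprocity and linearity are asserted strictly.  Convergence toward the
converged-mesh values is monitored across two mesh-scale levels (scales 8
and 6).

What the desk-scale conditions do *not* probe: sub-nanometre groove
resolution (the lubrication layer is represented by a single element
across the gap), fibre lengths above 80 nm in FEM runs, and
workstation-resolution meshes (scale 1 with a 10x outer boundary), which
the configuration supports but which take hours rather than minutes.

## Known limitations

* The point-Delaunay mesher yields boundary slivers; robustness comes from
  the direct solver and the variational load evaluation, not from mesh
  quality bounds.  No boundary layers or anisotropic refinement.
* The direct traction route is low-order; quantitative loads should use
  the variational route.
* Model 2 treats the fibre as rigidly guided by the groove (no lateral
  dynamics); only the axial force and torque balances are imposed, as in
  the underlying mechanical model.
* The transient wrapping stage of phage attachment and unsteady
  (linearised Navier-Stokes) effects are out of scope.
* Chirality antisymmetry of the FEM route is exact only up to mesh mirror
  symmetry; the suite verifies it by explicitly mirroring the discrete
  system rather than by re-meshing.
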