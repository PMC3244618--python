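# Methods

## Model

`cathsim` simulates a catheter or guidewire navigating a rigid, triangulated
blood-vessel surface as a sequence of static equilibria: each push or pull
input from the operator moves the system from one minimum of the total
potential energy to the next.  There are no inertial dynamics — the model is
quasi-static, which matches how slowly catheters are actually advanced.

The total potential of a configuration is

    Pi = U_e + U_p - W

with three terms:

* **Bending energy** (Kirchhoff rod, no torsion).  The centerline x(s) is
  represented by its tangent field t(s) = x'(s), and the bending energy
  `alpha * integral (t'(s))^2 ds` is discretized with piecewise-linear
  interpolation of t over N-1 elements of length h_i:

      U_e = alpha * sum_i ||t_i - t_{i-1}||^2 / h_i .

  Twist is excluded: clinical catheters transmit torque almost rigidly, so
  the torsional DoF is effectively infinitely stiff.  A factor 1/2 in the
  continuum form is absorbed into `alpha`; only the ratios
  alpha : kappa : |f| shape the minimizer.

* **Wall penalty** (Hooke's law).  The vessel wall is a triangle mesh whose
  per-triangle planes are stored as inward unit normals n and offsets d, so
  g(x) = n·x + d is positive inside the lumen.  A detected node-triangle
  contact j contributes `1/2 * kappa * g(x_j)^2`.  The wall never deforms
  geometrically; its compliance is represented entirely by the penetration
  allowed by finite kappa.

* **External work**.  Nodal forces f_i contribute W = sum f_i · (x_i - x_i0)
  with x_i0 the node's position at the previous equilibrium.  The potential
  *subtracts* W (the standard total-potential convention) so that forces pull
  nodes along their direction; the opposite sign, in which the work term is
  added, is selectable via `SolverConfig.sign_convention="work_added"`.
  Purely kinematic navigation (push/pull only) carries no external forces, so
  the choice is then irrelevant.  Friction is neglected: hydrophilic coatings
  make it small against bending and contact forces.

## Discretization and unknowns

The catheter is N nodes joined by N-1 elements.  The *unknowns are the nodal
tangents* t_1 … t_{N-1}; the base pose (x_0, t_0) is a fixed boundary
condition representing the introducer sheath.  Positions are recovered by
trapezoid integration (exact for linear interpolation):

    x_i = x_{i-1} + (h_i / 2)(t_{i-1} + t_i)

or in stacked form x = B t + c with B block-lower-triangular and nonsingular
(diagonal blocks (h_i/2) I). Every energy term is then a quadratic form
`1/2 t^T H t + g^T t + const`, stationarity gives the SPD linear system
A t = b, and the equilibrium is one dense Cholesky solve.  Solving in tangent
space and mapping through B is algebraically identical to composing the
position-space system A B^{-1} x = b, without forming B^{-1}; the composed
form is kept as a cross-check test.

Tangents are **not constrained to unit norm** — the constraint would destroy
linearity.  Two consequences, both measured and reported per step:

* `tangent_norm_drift` = max |‖t_i‖ - 1| grows where the catheter is loaded
  axially (a few percent in smooth navigation, tens of percent when stalled
  against an obstruction);
* the geometric arc length of the reconstructed polyline is slightly below
  the nominal inserted length, i.e. the model "compresses" instead of
  buckling under axial load.  This is inherent to the formulation, not a
  solver artifact.

Push/pull inputs of stepsize h < l are absorbed by a single variable-length
*base element*: the element at the sheath grows/shrinks with each input, and
a node is inserted (with tangent t_0) or removed when it crosses the segment
length l.  All energy integrals use per-element lengths, so the partial
element is handled exactly.

## Contact detection

Contact is node-based, matching the energy model: node i (i >= 1) contacts
triangle T when its signed plane distance is below the detection margin *and*
its orthogonal projection onto T's plane falls inside T (barycentric test,
edge tolerance 1e-9).  Detection is a vectorized all-pairs test with an AABB
prefilter and is exactly equivalent to brute-force enumeration (a tested
invariant).  A node may contact several triangles at creases; each contributes
its own penalty term.  The public `detect_contacts` default margin is 0
(penetration only).

Tunneling between nodes is mitigated by configuration validation (h <= l and
l below the vessel radius produce a warning otherwise), and by the generator
placing facet centers, not vertex seams, on the bend plane — a catheter
confined to the symmetry plane of a curved tube otherwise crosses the wall
exactly where the plane-projection test has a gap.

## The equilibrium loop

Because the penalty terms depend on positions that the solve itself changes,
each input is answered by an active-set iteration (a reconstruction of the
method's overall algorithm from its energy terms):

1. detect contacts at the current positions;
2. assemble the quadratic forms and solve A t = b;
3. reconstruct positions and re-detect;
4. stop when the re-detected set matches the assumed one and no contact's
   penetration moved by more than `active_set_tolerance` (1e-6 mm).

Three robustness devices were required in practice:

* **Merit line search.**  The plain detect/solve map oscillates between
  distant active sets (and can tunnel through the wall).  Each solve is
  treated as a generalized Newton step on the merit potential — smooth terms
  plus the Hooke penalty of currently detected contacts — and backtracking
  keeps every iteration a descent step.
* **Contact envelope.**  `SolverConfig.contact_margin` defaults to 1e-3 mm.
  With strict penetration-only detection an incipient contact (equilibrium
  |g| ~ 0) sits exactly on the active/inactive boundary and the set provably
  never settles; a micron-scale band keeps it active.  The extra |g|^2
  penalty inside the band is bounded by kappa * margin^2 / 2 per contact,
  far below the energies of interest.
* **Crease handling.**  Against a faceted wall the merit potential is
  nonsmooth across facet-prism boundaries, so the minimizer cannot be
  localized below the crease scale.  Period-2 relabelings between
  geometrically equivalent triangles are accepted as converged, and an
  iterate whose positions stop moving on the `stagnation_tolerance` scale
  (1e-3 mm) is finalized by one exact solve against the glued set of all
  wall planes within that distance, guarded by an energy check so the
  finalize can only confirm the configuration, not jump away from it.

A step can still end `converged=False` — typically when the minimizer hovers
just inside the wall with an empty active set (the compression artifact
relieving contact).  Non-convergence is recorded in the trace with the full
residual, never raised and never silently accepted; converged results always
satisfy ‖A t - b‖ <= 1e-10 (1 + ‖b‖) for their reported active set.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| alpha | bending constant (energy·mm) | 1 | only ratios matter; working units |
| kappa | wall stiffness (energy/mm^2) | 100 | behavior tests sweep 10…10^4 |
| l | segment length (mm) | 1 | keep below the vessel radius |
| h | input stepsize (mm) | l/5 | must satisfy h <= l |
| margin | solver contact envelope (mm) | 1e-3 | see above |
| max_outer_iterations | active-set cap | 50 | 1 reproduces a single-pass solve |

Millimeters throughout; 0-based indices in memory (OBJ files are 1-based on
disk).

## Synthetic phantoms

`make_tube` generates straight and planar-curved tubes (entry straight,
circular bend, exit straight), optionally capped, emulating the transparent
plastic-tube phantoms used to validate such simulators.  Two study phantoms
are fixed in the test suite and acceptance script:

* a **tight bend** (3 mm lumen radius, 90° bend of 12 mm radius) for
  contact-rich navigation, stiffness sweeps, stationarity checks and
  equivariance;
* a **gentle bend** (3.5 mm lumen radius, 60° bend of 20 mm radius) for the
  discretization-convergence sweep, pushed 18 mm at h/l = 1/5.  In this
  smooth-contact regime the equilibrium is discretization-stable and the
  sweep isolates pure discretization error (observed O(l^2)); in a stalled
  tight bend the trajectory is instead dominated by contact-set and
  compression path effects that do not converge with l.

What the phantoms do not emulate: branching (bifurcations), non-circular or
deforming lumina, pulsatile flow, friction, and patient-specific geometry.
Passing tests therefore demonstrate the numerical correctness and qualitative
behavior of the method, not clinical accuracy on real vasculature.

## Reference solutions and metrics

Physical ground truth is replaced by a high-resolution solver run (segment
length l/8, same phantom and total advance).  Comparison follows the
deformation metrics used for such validations: per-node Euclidean distances
against the reference resampled at the simulation's segment length, reduced
to RMS and maximum displacement.  Because solver nodes are material points
whose geometric spacing drifts below l (compression), the reference is
resampled by *node stride* when its grid nests the cell grid — the
material-consistent correspondence — and by geometric arc-length
interpolation otherwise.

## Numerical choices

* Dense Cholesky (`scipy.linalg.cho_factor`) with one step of iterative
  refinement; systems are 3(N-1) <= ~10^3.
* Non-SPD systems raise an error naming the near-null direction.
* Symmetrization of every quadratic form at construction; H is exactly
  symmetric.
* Degenerate triangles (area < 1e-12 mm^2) are dropped at load with a
  warning; loaded meshes are re-oriented inward by a majority vote of
  ray-parity tests from triangle centroids (assumes consistent winding).
* All randomness lives in tests and the acceptance script; the solver itself
  is deterministic, and reruns produce byte-identical traces.

## Known limitations

* No torsion, no pre-curved tips, no friction, no self-contact.
* Axial compression in place of buckling (unconstrained tangent norms).
* Node-based contact can, in principle, miss wall crossings between nodes for
  coarse discretizations (warned about in config validation).
* Equilibria against faceted walls are resolved only to the facet-crease
  scale (~`stagnation_tolerance`).
* The vessel wall is rigid; wall compliance exists only through the penalty.
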