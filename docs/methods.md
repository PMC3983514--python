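# Methods

## The model

`cardiobuckle` simulates the growth-induced buckling of an elastic rod
confined between a rigid hemispherical dome and a plane floor — a
desk-scale mechanical analogue of cardiac looping, in which the straight
embryonic heart tube is transformed into a helically wound loop by
compressive loads arising from the heart growing faster than its
pericardial cavity.  The apparatus the default configuration encodes: a
hemisphere of inner diameter 136 mm (the ventro-lateral "pericardial"
walls) standing on a plane stage (the dorsal wall), with two antipodal
openings — the cranial and caudal ports — through which a silicone-rubber
rod of diameter 23 mm and total length 480 mm passes.  Initially a
~136 mm portion of the rod spans the cavity; quasi-static "growth" feeds
additional rod length in through the cranial port, 1 mm at a time, to a
final intra-cavity length of 350 mm.

Coordinates are right-handed: +x cranial→caudal, +y embryo-left,
+z ventral (the dome occupies z > 0).  All lengths are millimetres.

### Elastic rod

The rod is a discrete Kirchhoff rod: a polyline of nodes with per-edge
rest lengths, isotropic bending, and decoupled quadratic energies

* stretch `½ k_s Σ (|e_i| − ℓ_i)²/ℓ_i` — a numerical penalty keeping the
  rod near-inextensible (`k_s = 10` in bend units keeps equilibrium
  strains below 0.1 %; buckling forces in this geometry are ~10⁻²–10⁻³);
* bend `(B/2) Σ |κb_i|² / ℓ̄_i` with the curvature binormal
  `κb_i = 2 e_{i−1}×e_i / (|e_{i−1}||e_i| + e_{i−1}·e_i)`,
  `|κb| = 2 tan(φ/2)` for turning angle φ; `B = 1` sets the energy unit
  (shapes of a near-inextensible rod without gravity are
  modulus-independent);
* twist, treated quasistatically: with both end clamps preventing axial
  rotation, the material twist relaxes to uniform density and contributes
  `C Θ²/(2L)`, where Θ is the angle between the caudal clamp director and
  the cranial director parallel-transported along the centerline, unwrapped
  continuously from step to step (quasi-static continuation conserves the
  2π branch, as the physical clamps cannot spin).  The positional force
  from Θ is the holonomy gradient, assembled from the curvature binormals.
  `C/B = 2/3` is the isotropic-rod value 1/(1+ν) for incompressible
  rubber (ν = ½).

Gravity, when enabled, adds `w Σ ℓ̄_i z_i`.  The default
`w = 5.4·10⁻⁷ mm⁻³` (in B = 1 units) is derived from the physical rod:
Shore A 17 ≈ 0.6 MPa Young's modulus, silicone density ≈ 1.15 g/cm³,
giving a gravito-bending length (B/w)^⅓ ≈ 120 mm — comparable to the
apparatus, which is why the unconfined rod eventually flops under its own
weight.  Gravity is off by default in the confined experiments; we
verified that enabling it at this weight changes neither the phase
sequence nor the transition lengths, so the confined runs are reported
without it.

### Boundary conditions

Clamps are hard constraints, not penalties.  The end nodes are fixed at
the ports and the first/last *edge direction* is fixed along the clamp
axis (tilted 10° toward the mid-ventral dome, so planar bending is
consistently directed ventrally — the printed description says only
"slightly tilted"; the angle is a config value).  The first/last edge
*length* is a sliding degree of freedom: the rod feeds through the port.
In the free-caudal mode the whole caudal clamp may additionally translate
along y (the left-right rail), up to a configurable rail travel
(±50 mm default, a solver guard well inside the cavity radius).

### Contact

Walls are rigid and frictionless (the physical rod was powder-coated
precisely to minimize friction); penetration of the rod surface is
penalized by one-sided quadratic energies on the node clearances to the
dome sphere and the floor plane.  Nodes within an angular window (14°)
around each port axis are exempt from dome contact — the rod passes
through the openings; in the free-caudal mode the caudal window follows
the rod's actual exit point (the physical opening is a slot).
Self-contact uses segment–segment distances between non-adjacent edges
(edges closer than ~3 rod radii of arclength are never candidates — the
surface cannot meet itself over so short a geodesic distance) and switches
on once the fed length approaches helical onset.  If an equilibrium
exceeds the non-penetration tolerance (5 % of the rod radius) the penalty
stiffness is escalated tenfold and the solve repeated.

A regularized Coulomb friction force is available for sensitivity
studies only; every reported experiment is frictionless.

### Quasi-static growth and equilibrium

Each growth step adds one feed increment of rest length at the cranial
edge (inserting a node when the edge exceeds 1.5× nominal spacing),
applies seeded zero-mean lateral noise to the interior nodes while the
configuration is still planar (RMS 0.065 mm, see below), and relaxes to
equilibrium with L-BFGS-B on the free coordinates using the analytic
gradient.  The initial guess for each solve distributes the fed increment
along the rod (arclength resampling plus the inextensible-bow amplitude
relation, with a secant continuation term); the minimizer does the
physics.  Equilibria are accepted at a gradient infinity-norm of 10⁻⁴
(bend-unit forces); helical-phase equilibria have nearly-flat modes — the
coil sliding on the frictionless dome — and tightening the tolerance
tenfold multiplies iteration counts sixfold while changing the writhe by
less than 0.01.  Non-converged solves raise a flagged failure carrying
the best state; growth loops record and truncate, never silently drop.

All randomness enters through the perturbation seed; the solver itself is
deterministic, and every floating-point reduction is even in the mirrored
(y) coordinates, so negating the caudal offset and the noise stream
yields the bitwise-mirrored trajectory with the opposite handedness label.

## Morphometrics

**Writhe** is the exact discrete Gauss double integral over non-adjacent
segment pairs (the Levitt / Klenin–Langowski closed form).  In this frame
a right-handed helix has positive writhe; the D-loop (left-handed helix)
is negative.  The handedness *classifier* evaluates writhe on a lightly
smoothed resampling of the centerline (box window, 5 % of arclength) so
node-level jitter cannot masquerade as coiling, with a dead zone of 0.05
on either side of zero reported as indeterminate.

**Torsion sign profile**: the centerline is resampled at an arclength
step of 5 % of its length after the same smoothing, and the normalized
triple product of consecutive tangents gives a per-window sign (dead zone
5·10⁻³).  Persistent runs must cover ≥15 % of arclength, counting one
smoothing window per sample.

**Phase classification**: STRAIGHT if every node is within 5 % of the
cavity radius of the end-to-end chord; SINUSOIDAL if bent but with
out-of-sagittal RMS below 5 % of the cavity radius; otherwise the state
is spatial and must actually *coil* to be helical: winding about the
cranio-caudal port axis (net ≥20° for SIMPLE_HELICAL with single-signed
persistent torsion, excursion ≥20° for COMPLEX_HELICAL with persistent
runs of both signs).  The winding requirement distinguishes a leaning —
still planar — loop (which neither winds nor coils, e.g. the unconfined
gravity flop) from genuine helical buckling; a bent spatial state that
does not qualify remains SINUSOIDAL.

**Transitions**: phase labels along a trajectory are median-filtered
(width 3).  The helical onset is the first (simple or complex) helical
state.  The complex onset is the start of the terminal contiguous
complex block: the planar-to-spatial snap-through passes transiently
(~180–200 mm) through two-handed shapes before consolidating into the
single-handed helix, and the sustained two-handed configuration is the
one the transition length describes — matching how the physical
transition was scored from sustained configurations, not from
reconfiguration transients.

**Perversion location**: the junction between the dominant opposite-sign
torsion runs, with the handedness of the cranial and caudal limbs.

## The chirality ensembles

Symmetry is broken by the caudal-end offset (signed, +y = leftward) and
by the seeded lateral micro-noise that emulates apparatus imperfection.
Following the calibration protocol, the noise amplitude was calibrated
once — midline ensembles statistically 50/50 (they are 50/50 in
distribution by symmetry for any amplitude) and the 1 mm-offset ensemble
reproducing a small minority of opposite-handed outcomes — and then
frozen at 0.065 mm RMS for every condition.  Ensembles use a coarser
discretization (9 mm node spacing, 3 mm feed increments, stop at 200 mm):
handedness is decided at the sinusoidal-to-helical bifurcation near
175 mm and locked well before 200 mm, so the tail of the growth adds cost
but no information.  Problem sizes: a full confined run uses ~90 nodes
and 214 feed steps; an ensemble run ~22 nodes and 22 steps.

## Free-caudal coupling

With the caudal clamp free to slide laterally, the emerging helix drags
the caudal end toward the side matching its handedness (left-handed
D-loop → leftward).  The coupling is read at the last recorded state with
determinate handedness of a run stopped near 200 mm: during the
snap-through itself the end can transiently kick the other way, and far
beyond onset the large displacement reorganizes the coil (the model's
frictionless end slides much farther than the physical sledge moved).

## The synthetic fixtures

`fixtures.generate_fixture` produces the idealized centerlines the
classifiers must recognize: straight tubes, cavity-scale planar arcs,
single-handed helices of either chirality, and a two-handed helix whose
mirror-image limbs join with tangent continuity (the perversion's
inflection).  These are analytic curves, optionally with seeded node
jitter; they emulate idealized loop geometries, not equilibria of the
rod model, so classifier tests on them validate the morphometrics, not
the mechanics.

## Independent oracles used in the tests

* writhe: dense Riemann quadrature of the Gauss double integral on smooth
  parametric helices, Richardson-extrapolated;
* pinned-pinned buckled column: elastica closed form via elliptic
  integrals (midpoint deflection), against the discrete minimizer in
  pinned mode;
* dome-touch length: a planar clamped-clamped elastica integrated by RK4
  shooting, grown until its surface first reaches the dome outside the
  port windows.  This brackets the helical onset from below and agrees
  with the simulator's own first dome contact to better than 1 %; the
  *classified* onset follows a few millimetres later, after the pressed
  planar bow loses lateral stability;
* self-contact pair lists against a brute-force all-pairs scan;
* analytic gradients against central finite differences.

## Numerical choices and degenerate inputs

Duplicate consecutive nodes, zero rest lengths and 180° edge fold-backs
raise degenerate-geometry errors.  Stale reference frames (tangent
mismatch beyond 10⁻⁸) are rejected by `twist_energy`.  The twist branch
is unwrapped toward the previous step's value; ties in `round` cannot
occur away from exact half-turn jumps.  Contact windows make the energy
only piecewise-smooth at window boundaries; L-BFGS-B tolerates this at
quasi-static loading.

## Known limitations

* The model is frictionless; the physical rod, though powder-coated, had
  residual friction.  The frictionless coil slides freely on the dome,
  which makes helical equilibria nearly neutral along sliding modes and
  lets the free caudal end travel farther than the physical sledge.
* The snap-through at helical onset passes through transient two-handed
  shapes that the physical protocol (scoring sustained configurations)
  would not record; transition reporting accounts for this explicitly.
* In the late complex phase the opposite-handed torsion segments of the
  wall-pressed coil wind about the port axis less than idealized helical
  limbs would; the classification follows the torsion-run definition.
* Penalty contact permits ≤5 % rod-radius penetration; rigid-wall limits
  would shift transition lengths by a comparable relative amount.
* Ensemble statistics are reported at the coarse discretization; the
  bifurcation physics (offset vs noise competition) is resolution-robust
  in sign, but per-seed outcomes differ between resolutions.
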