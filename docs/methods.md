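# Methods

## Model

A vascular network is an undirected graph with degree-1 boundary nodes
(inlets and outlets, carrying prescribed pressures) and degree-3 interior
junctions.  Each vessel (x, y) has a length L_(x,y) (stored as a multiple
of a reference length L, which never needs a numeric value), a diameter
D_(x,y) in µm, and carries a volumetric flow

    Q_(x,y) = (P_x − P_y) / R_(x,y),
    R_(x,y) = 128 L_(x,y) µ(H_(x,y), D_(x,y)) / (π D_(x,y)^4),

with the in-vivo apparent viscosity

    µ(H, D) = µ_p [1 + (µ45 − 1) · ((1−H)^C − 1)/(0.55^C − 1) · W] · W,
    W = (D/(D − 1.1))²,
    µ45(D) = 6 e^(−0.085 D) + 3.2 − 2.44 e^(−0.06 D^0.645),
    C(D) = (0.8 + e^(−0.075 D)) (−1 + 1/(1 + 10⁻¹¹ D¹²)) + 1/(1 + 10⁻¹¹ D¹²).

H is the vessel haematocrit (RBC volume fraction).  Junction rules:

* every interior node conserves blood flow (Kirchhoff),
* a converging junction (2 in, 1 out) conserves RBC flux,
* a diverging junction (1 in, 2 out) distributes RBC flux by the Pries-1990
  splitting rule ψ(r) (logit form with coefficients A, ρ, X0 that depend on
  the parent haematocrit and the three diameters).  The rule satisfies the
  partition of unity ψ_d(r) + ψ_s(1−r) = 1, so the two per-daughter
  equations imply nodal RBC conservation.  Below the threshold flow
  fraction X0 = 0.4/D_parent a daughter receives no red cells at all —
  this is why "intermediate-flow" cross vessels run essentially empty.

Unknowns: interior pressures and the haematocrits of all non-inlet vessels
(inlet-vessel haematocrits are boundary data).  Flows are eliminated via
Poiseuille's law and reported normalised by the total inflow Q_in, so
|Q| ≤ 1; pressures can be normalised to (P − P_out)/(ΣP_in).  In these
variables the equilibria are invariant to the plasma viscosity µ_p, the
reference length L and uniform rescaling of the boundary-pressure span
(verified by tests); µ_p therefore defaults to 1.  Diameters cannot be made
dimensionless — the viscosity and splitting laws set a µm scale — and are
stored as numbers of µm.

The equation attached to a vessel's haematocrit follows the junction type
at its *current* upstream node, re-detected from the flow signs at every
residual evaluation (flows below 10⁻¹⁴ are treated as zero and directed
along the vessel's reference orientation).  Off-equilibrium iterates can
visit unphysical configurations (a junction with no inflow, a reversed
outlet vessel); those vessels get the regular pinning equation H = 0,
which is full-rank and only active transiently.

## Canonical networks

* Triangle: inlets 1, 2 (P = 0.5, H_in = 0.45) feed interior nodes 4, 5,
  joined by the redundant cross vessel ⟨4,5⟩ of length αL; vessels (4,6)
  (length βL) and (5,6) lead to the outlet vessel (6,3) (P₃ = 0).
* Extended triangle: a second cross vessel ⟨7,8⟩ (also αL) and feed
  vessels (7,4), (8,5) inserted between the inlets and the triangle core.

Defaults α = 0.1, β = 1, D = 10 µm for all vessels.  β ≠ 1 breaks the
left/right mirror symmetry.  With r redundant vessels the network admits at
most 3^r equilibria, labelled by the flow state (−/0/+) per redundant
vessel; the label "intermediate" (0) is assigned relationally — the middle
member of a triple of coexisting flows straddling zero — not by a sign
threshold, because away from exact symmetry the intermediate state carries
a small nonzero flow.

## Numerics

* **Newton**: damped (backtracking halving, ≤ 20 halvings), finite-difference
  Jacobian (central, step 10⁻⁷(1+|x|)), haematocrit iterates clipped to
  [0, 0.999] during iteration only; convergence at residual ∞-norm < 10⁻¹².
  Exactly singular Jacobians (a zero-flow cross vessel leaves its
  haematocrit column zero at symmetric states) fall back to the
  minimum-norm least-squares step.
* **Homotopy start**: the starting system G freezes every viscosity at
  µ(H_in, D) and pins all haematocrits to H_in (linear in P, unique
  solution); h = (1−λ)F + λG is traced from λ = 1 to 0.
* **Branch tracing**: pseudo-arclength predictor–corrector; tangents from
  the bordered Jacobian, corrector Newton orthogonal to the tangent;
  adaptive steps in [10⁻⁸, 2·10⁻²] (sweep drivers default to 6·10⁻³, the
  inlet-haematocrit critical-value search to 3·10⁻³ — the inner fold
  structures are a few 10⁻³ wide and wider steps can hop over a fold
  pair).  Corrector excursions far from the predictor are rejected to
  prevent branch jumping.  Traces that stop progressing (25 consecutive
  displacements < 10⁻⁸) terminate as "stalled"; this happens where a branch
  ends on the symmetric base branch at a symmetry-breaking branch point,
  where the bordered system is singular.
* **Folds**: detected as sign changes of the tangent's parameter component,
  bracketed by bisection along the branch, then polished by Newton on the
  extended fold system (F = 0, Jv = 0, v_k = 1), which leaves the Jacobian
  singular to ~10⁻¹² relative at the reported point.  The polish is
  rejected if it leaves the bisection bracket's neighbourhood.  Folds found
  repeatedly (the same closed curve traced from several seeds) are merged
  when both the parameter (10⁻⁴) and the state (10⁻⁴ ∞-norm) agree;
  mirror-image fold pairs at equal parameter values remain distinct.
* **Enumeration**: union of (a) multistart damped Newton from a scrambled
  Sobol grid over the box P ∈ [P_out, P_in], H ∈ [0, ~0.72] plus the
  zero-haematocrit and frozen-haematocrit linear solutions, and (b)
  continuation seeding — trace the inlet haematocrit up from the unique
  H = 0 solution, then repeatedly trace every known equilibrium through β
  and α and collect all branch crossings of the target value.  States are
  canonicalised (haematocrit of a zero-flow, sub-threshold cross vessel set
  to its continuous limit 0 — the equations leave it undetermined there)
  and de-duplicated at 10⁻⁶ ∞-norm.  Both routes independently recover all
  9 extended-triangle equilibria at the defaults; the pure continuation
  route cannot be complete on its own at exact symmetry, where some
  branches connect to the base state only through symmetry-breaking branch
  points that arclength tracing does not switch onto.
* **Region maps** count equilibria per grid cell by warm-started Newton
  (carrying the neighbouring cells' equilibria as initial guesses, plus
  random and perturbation batches, escalating while the count is even —
  equilibria appear in pairs above the unique base state).  Grids avoid
  β = 1 exactly, where the symmetric states are degenerate.
* **Critical curve H^(3)(D)**: the (+,+) equilibrium is found at a high
  inlet haematocrit (0.6) and continued downward; H^(3) is the lowest fold
  on that branch, or, at large diameters where the branch instead
  terminates on the symmetric base branch, the lowest haematocrit reached
  before the trace stalls.  The diameter grid is 20 points, log-spaced over
  [10, 200] µm, with a local quadratic refinement around the maximum.

## Problem sizes and determinism

All computations are desk-scale: 7 unknowns (triangle) or 12 (extended
triangle); a full β sweep is a few hundred to a few thousand corrector
solves.  Default multistart sizes are 200–300 (triangle) and 600 (extended
triangle) Sobol starts, which recover the known 3 and 9 equilibria with
margin; region maps use ~25 random starts per cell on top of warm starts.
Every random draw is seeded; repeated runs with the same seed are
bit-identical.

## What the fixtures do and do not emulate

The canonical networks reproduce the study geometries exactly.  The random
small networks (grown from a Y junction by T-insertions and loop-creating
bridges, with random lengths, diameters, pressures and inlet haematocrits)
exercise the structural code paths — validation, orientation enumeration,
redundancy detection, conservation — on irregular degree-3 topologies.
None of the fixtures emulate real capillary beds: no vessel compliance, no
diameter heterogeneity along a vessel, no RBC transit-time dynamics, no
oxygen transport.  Passing tests therefore demonstrate correctness of the
steady-state model and its continuation machinery, not physiological
fidelity of any particular network.

## Known discrepancies and limitations

* The implementation reproduces the published fold locations of the
  triangle network (0.963, 1.039), the six inner folds and the upper outer
  fold (2.343) of the extended triangle, the first critical haematocrit at
  D = 10 (0.322) and the equilibrium counts 3/9 — but the *lower* outer
  fold of the extended triangle computes to β = 0.411 rather than the
  reported ≈ 0.35.  An independent 800-start multistart confirms a unique
  equilibrium below β ≈ 0.41 under this model, so the value is not a
  continuation artifact; the corresponding multiple-equilibria interval
  ratio between the two networks comes out at ≈ 25, consistent with the
  printed fold locations arithmetic.
* Stability of equilibria, oscillatory dynamics and junctions of degree
  > 3 are out of scope.  Labelling of coexisting equilibria relies on
  clustering flows per redundant vessel; at parameter slivers where two
  same-labelled equilibria coexist briefly the labelling flags ambiguity
  rather than resolving it.
* Only the Pries-1990 splitting rule (and a linear "proportional" reference
  rule) is implemented; alternative empirical rules can be registered
  through the same interface but no coefficients are shipped for them.
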