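# Methods

This note records the model assumptions, the numerical choices and the
design decisions behind `stabscape`, at the level of detail a maintainer or
a cautious user needs. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and assumptions

The package analyses autonomous systems `dx/dt = f(x; a)` with rational
rate functions over exact rational coefficients, `n ≥ 1` state variables
and `k ≥ 1` positive parameters. Steady-state analysis assumes the cleared
polynomial system has finitely many isolated complex solutions at generic
parameters; a rank-deficient (positive-dimensional) solution set raises an
explicit error rather than returning partial output. Rational rates are
handled by clearing denominators; this is valid where denominators do not
vanish, so every returned solution is checked against the denominator zero
sets. Solutions on a denominator zero set are artifacts of clearing and are
dropped; a *positive* candidate on a denominator zero set raises an error,
because it would mean the model itself is ill-defined on the set of
interest.

## Stability and Routh polynomials

Local asymptotic stability is decided by the Routh-Hurwitz criterion on the
monic characteristic polynomial `λ^n + c_{n−1} λ^{n−1} + ... + c_0` of the
Jacobian. The Hurwitz matrix convention is `H[i][j] = c_{n−2i+j}` in
1-based indices with out-of-range coefficients set to zero; the criterion
is positivity of the leading principal minors `Δ_1 .. Δ_{n−1}` together
with `c_0` (equivalent to positive definiteness, since `Δ_n = c_0 Δ_{n−1}`).
For `n = 2` this reduces to `c_1, c_0 > 0` (trace negative, determinant
positive) and for `n = 3` to `c_2 > 0`, `c_2 c_1 − c_3 c_0 > 0`, `c_0 > 0`,
which the tests verify symbolically. General `n > 4` is out of scope beyond
the minor construction.

Verdicts use a tolerance of `1e-9` on Routh-polynomial values; a value
within tolerance of zero yields the verdict `boundary`, never a silent
classification. Every numeric verdict is cross-checked against the
eigenvalue real parts; disagreement (which would indicate a convention
error) raises instead of returning.

## Equilibrium-ideal decomposition

Full primary decomposition is replaced by recursive factor splitting: each
cleared rate polynomial is factored after substituting the coordinates
already forced to zero on the current branch, and the branch splits on each
factor. This is sufficient for per-capita-structured ecological models,
whose rates factor as `variable × cofactor`; the Levins-Culver system
splits into its four known components and the reduced coral model into its
five equilibrium types. Branches whose ideal is inconsistent are pruned
(Groebner basis `{1}`); duplicates and variety-contained components are
removed; components lying inside a rate-denominator zero set (artifacts of
clearing, e.g. `1 + βx = 0` in the Holling Type II model) are dropped. A
generator that remains reducible on a finished branch is kept with a
warning — the component may be mixed, but the union of varieties is still
correct. User-supplied component lists are accepted as an escape hatch.

Component labels are generated from the zero-coordinate pattern: `E_0` when
all variables vanish, `E_co` when none is forced to vanish, otherwise
`E_` followed by the initials of the surviving variables (`E_xy`, `E_xz`,
...). Display names for stable-state sets are generated from the singleton
vocabulary; sets are keyed by the label set itself and the names are
cosmetic.

## Elimination

Boundary ideals are eliminated per component and per extra polynomial (one
Routh polynomial, the Jacobian determinant, or one coordinate at a time),
which is much cheaper than a monolithic elimination. The default strategy
solves generators that are linear in a variable (with a pivot coefficient
free of the remaining unknowns) by exact substitution — valid on an
irreducible component where the pivot is not identically zero — and
eliminates at most one leftover variable by a Sylvester resultant; anything
less structured falls back to a lexicographic Groebner basis with the state
variables ordered first. Resultants can in principle contribute extraneous
factors from vanishing leading coefficients; for the shipped fixtures the
two strategies are compared in the tests. Results are reduced to squarefree
irreducible factors over Q and canonicalized to coprime integer
coefficients with a positive leading coefficient under graded reverse-lex
order, which is also the deduplication key.

An elimination whose parameter-only ideal is zero is reported with a
`zero` sentinel (every parameter admits such a solution — e.g. the
coordinate boundary of a variable identically zero on the component); an
ideal of codimension two or more contributes no hypersurface and is logged,
not silently dropped. Each elimination call can be capped by a wall-clock
timeout (default 600 s in the CLI) running in a forked subprocess; a
timeout names the component and boundary type. The full 6-parameter coral
boundary is out of scope for desk-scale hardware.

For positive-orthant work, factors whose nonzero coefficients all share one
sign are dropped from the *routing* arrangement (they cannot vanish at
strictly positive parameters, so they contribute no wall); the reported
arrangement keeps them.

## Routing functions

The routing function for an arrangement `g_1 .. g_m` restricted to the
positive orthant is `r_c = ∏ g_i · ∏ a_j / (1 + |a − c|²)^D` where the
coordinate factors are added only if not already arrangement members, `D`
is minimal with `2D` above the numerator degree, and `c` is drawn uniformly
from `(0.5, 1.5)^k`, rationalized (denominator `2^20`) so the exact
resultant path stays exact.

All numerics evaluate the function in **factored log form**: with
`L = Σ log|g_i| − D log den`, the gradient is `∇r = r ∇L` and the Hessian
`H = r (∇L ∇Lᵀ + HL)`, every term of which involves only the low-degree
factors. This avoids expanding products of degree 50+ (coral slices) and
keeps evaluation overflow-free at any distance from the origin. Critical
points off the boundary are exactly the zeros of `∇L`, which is the system
Newton iterates on; near the boundary `∇L` has poles, so Newton is pushed
away from walls rather than onto them.

Two solver routes exist behind one interface, and fixture counts are
checked to be solver-independent:

* `k ≤ 2`, numerator degree ≤ 12: the cleared-denominator gradient system
  (each equation of degree `deg + 1`) is solved by an exact Sylvester
  resultant. The resultant is factored into irreducibles first and real
  roots are isolated per factor with exact interval arithmetic — a
  companion-matrix root finder on the raw degree-~50 resultant was observed
  to *miss* roots. Second coordinates come from both gradient equations'
  univariate restrictions, and all candidates are Newton-polished.
* otherwise: damped Newton on `∇L = 0` from three independent start
  batches (two scrambled Sobol sequences and one uniform batch, all seeded),
  so no single unlucky low-discrepancy draw can drop a critical point.
  Convergence demands a step below `1e-13` relative and a final residual
  `|∇L| < 1e-7 (1 + |a|)`.

Candidates are deduplicated at `1e-8` relative distance, excluded if any
numerator factor vanishes within `1e-10 (1 + |a|)^deg` (boundary points),
and restricted to strictly positive coordinates in orthant mode.

Classification uses the scaled Hessian `M = H / r = ∇L ∇Lᵀ + HL`: the
eigenvalues of `H` sharing the sign of `r` are exactly the positive
eigenvalues of `M`, so the index and the unstable eigenvector directions
are computed from `M` without ever forming `r` itself. The degeneracy
threshold is `1e-11` relative to the spectral radius: strongly anisotropic
sliver regions (nearly parallel walls, common in the coral slices)
legitimately produce eigenvalue ratios around `1e-8`, which a tolerance of
`1e-7` would misreport as degeneracy for *every* center; `1e-11` sits just
above double-precision arithmetic noise. Genericity of the center is
checked by pairwise distinctness of critical values (compared as
`(sign, log|r|)` pairs at `1e-9`); a failed check re-draws `c` with a new
logged seed, up to five times.

## Connectivity

The ascent flow integrated is `dy/dt = ∇L(y)`: since
`sign(r) ∇r = |r| ∇L` and `|r| > 0` off the boundary, its trajectories
coincide with the sign-corrected gradient flow up to time rescaling, while
remaining finite at any degree and repelling trajectories from walls
(`L → −∞` there). Saddle launches start at `point + ε v` with
`ε = 1e-4 (|point| + 1)`, halved until the first offset increases `|r|`.
Integration uses adaptive LSODA (`rtol 1e-9`) over doubling time chunks;
`log|r|` is checked to be nondecreasing at every accepted chunk. When
`|∇L|` falls below `1e-3 (1 + |y|)` the endpoint is Newton-polished and
matched to the nearest routing point within `1e-5` relative; a second
vertex within twice that distance is an ambiguity error, an endpoint norm
above `1e6` an escape error, both naming the start point. Landing at the
launching saddle itself is excluded until `log|r|` has strictly increased.
Membership queries (`locate`) integrate the same flow from the query point
after rejecting points within boundary tolerance.

Full-space counts (all orthants) are available by building the routing
function without coordinate factors (`restrict_positive=False`) and
widening the solver box; the positive-orthant mode is the tested,
desk-scale path, and the full-space Levins-Culver census is long-running
and not exercised by the default suite.

## Grid oracle

The independent check on region counts is a sign-vector flood fill over a
box grid. A naive face-adjacency fill fragments regions that are thin
relative to a cell (tilted sheets in 4-D lose face connectivity entirely),
so the oracle (i) marks cells adjacent to a sign change as *guard* cells
and counts only the interior, (ii) joins interior cells across the full
Chebyshev neighborhood (the guard layer prevents false diagonal merges at
transversal crossings), and (iii) re-joins components whose representatives
share a sign vector when a sampled constant-sign path — the straight
segment or a radial detour through scaled midpoints — connects them, which
repairs erosion splits of cone-shaped chambers pinched near the origin.
The count is reported only when unchanged under one resolution doubling,
and is flagged inconclusive after three unstable doublings or when the next
doubling would exceed the memory guard (20M cells). Representatives are
interior cells maximizing the minimal factor magnitude. The oracle is a
*lower-bound estimator with a stabilization certificate*: the routing graph
is the primary method, the grid its cross-check.

The random-arrangement generator used for the cross-validation property
draws lines through random rational points and axis-aligned rational
ellipses (nonsingular by construction), and rejection-samples until the
arrangement is *well separated*: no two crossing points closer than 0.5, no
crossings far outside the sampling box, and no curve-to-curve normalized
distance below 0.15 away from crossings. Separation guarantees that a
moderate-resolution grid resolves every region, so that grid/routing
disagreement indicates a real defect and not an oracle artifact. This is a
deliberate restriction of the test distribution: configurations with
near-tangencies or near-triple points are *not* covered by the property,
and real models can contain them — the slice machinery handles such
geometry through the log-form numerics, but its counts there rest on the
routing method alone.

## Slices and classification

A 2-D slice fixes parameters to exact rationals *before* factorization, so
that a boundary factor vanishing identically on the slice is detected
symbolically (dropped with a warning). The slice pipeline enumerates
regions of the full positive quadrant, not just the plotting window:
critical points outside the window are genuine regions and are reported;
the multistart box spans 1.5× the window, and Newton regularly converges to
critical points beyond it. Steady states at a representative are solved
per component by a triangular reduction mirroring the eliminator (linear
solves, then one univariate polynomial handled numerically), giving
millisecond classification per point. Each real solution is assigned its
component's type; a solution with a type-required coordinate within `1e-9`
of zero, or a `boundary` Routh verdict, flags the region near-boundary
rather than misclassifying it. Optional validation re-classifies
`locate`-confirmed interior samples and demands constancy.

Limit-cycle evidence for empty-stable-set regions is a numerically
integrated trajectory (LSODA, `rtol 1e-9`, default horizon 2000 time
units) summarized by boundedness, distance to the nearest steady state,
and a recurrence statistic (closest return of the tail to the final
state). It is evidence, not proof.

## Problem sizes in the default suite

The shipped tests run the two-ellipse example exactly; the Levins-Culver
pipeline with a 16k-start multistart in a `(0, 8]^4` box and the 4-D grid
at resolution 20 doubled to 40 on `(0, 3]^4`; twenty well-separated random
2-D arrangements at grid resolution 300; one thousand random rational
matrices for the Routh/eigenvalue agreement; and nine coral slices (the
eight non-viable-coral slices and the `b = 2, β_z = 41/10` slice). These
sizes were chosen to make the full suite a coffee-break run on one CPU
while still exercising every code path; the region counts they produce are
stable under enlarging any of them, which the stabilization and
seed-invariance checks enforce internally.

## Known limitations

* Recursive factor splitting is not a general primary decomposition; models
  whose components are not cut out by factorable generators need
  user-supplied components.
* Resultant-based elimination may contribute extraneous factors where both
  leading coefficients vanish; such factors over-segment the landscape but
  never merge genuinely distinct regions, and classification remains
  correct per region.
* Multistart critical-point search carries no completeness certificate
  (the exact resultant path does, for `k ≤ 2` at moderate degree); a missed
  extremum would undercount regions, which the grid cross-check guards on
  the tested fixtures.
* The grid oracle is limited to `k ≤ 4` and its witness-path merge can in
  principle miss a double wall crossing between samples.
* Equilibrium types are keyed by zero-coordinate patterns; models with
  symmetric or coinciding equilibria within one component are not
  distinguished.
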