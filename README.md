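# stabscape

Stability landscapes of parametric ODE models via routing functions on
hypersurface-arrangement complements.

## The problem

Ecological and biochemical models of the form `dx/dt = f(x; a)` — with
polynomial or rational rates `f`, nonnegative state `x` and positive
parameters `a` — change their qualitative behaviour only when the parameters
cross certain algebraic boundaries. Three kinds of boundary matter for the
number and type of *stable* steady states:

* the **singular boundary** (the discriminant locus), where a steady state
  becomes degenerate (`f(x; a) = 0` and `det J_x f = 0`) and the number of
  real solutions can change;
* the **Routh-Hurwitz boundary**, where a Routh polynomial (a leading
  principal minor of the Hurwitz matrix of the characteristic polynomial,
  or `c_0`) vanishes at a steady state, so a stability verdict flips;
* the **coordinate boundaries**, where a steady-state coordinate reaches
  zero and feasibility changes.

Their union, the *total boundary* `B = ∪ { a : g_i(a) = 0 }`, is a
hypersurface arrangement in parameter space. On each connected component of
the complement `R^k_{>0} \ B` the set of stable steady-state types is
constant, so enumerating and classifying these regions yields the whole
**stability landscape** of the model.

`stabscape` computes the landscape in four stages:

1. **Boundaries** — split the equilibrium ideal into components (one per
   equilibrium type, e.g. extinction / exclusion / coexistence) by recursive
   factoring, then eliminate the state variables from each component ideal
   plus one extra polynomial at a time (a Routh polynomial, the Jacobian
   determinant, a coordinate), collecting the irreducible parameter-space
   factors `g_1, ..., g_m`.
2. **Routing function** — form
   `r_c(a) = g_1(a)···g_m(a)·∏ a_i / (1 + Σ (a_i − c_i)²)^D`
   with a generic positive center `c` and `2D > deg` of the numerator.
   Its critical points ("routing points") off the boundary catalogue the
   regions: every region contains at least one, and the *index* of a point
   (Hessian eigenvalues sharing the sign of `r_c`) distinguishes extrema
   (index 0) from saddles.
3. **Connectivity** — from every saddle, follow the ascent flow
   `dy/dt = sign(r_c)·∇r_c` along both unstable eigenvector directions
   until it lands at another routing point. The connected components of the
   resulting graph are in one-to-one correspondence with the regions.
4. **Classification** — solve the steady states at one routing point per
   region, assign each to its equilibrium type by zero-coordinate pattern,
   and test stability with the Routh-Hurwitz criterion.

Shipped fixtures: a two-ellipse toy arrangement, a Holling Type II
predator-prey model with a strong Allee effect, the Levins-Culver
competition-colonization model, and a coral-bacteria symbiosis model
(parasitic and mutualistic symbionts on a dynamic coral host).

## Worked example

The two-ellipse arrangement
`g1 = (a1−5)² + 4(a2−5)² − 16`, `g2 = 4(a1−5)² + (a2−5)² − 16`
divides the positive quadrant into six regions:

```python
import sympy as sp
from stabscape import fixtures, build_routing_function, critical_points
from stabscape.connectivity import build_routing_graph

arr = fixtures()["two_ellipses"]
rf = build_routing_function(arr, c=(sp.Rational(6, 5), sp.Rational(7, 10)))
points = critical_points(rf)
graph = build_routing_graph(rf, points)
print(len(points), sum(p.index == 0 for p in points),
      sum(p.index == 1 for p in points), graph.n_components)
```

prints `9 7 2 6`: nine routing points, of which seven are local extrema and
two are saddles; the gradient-flow graph connects them into exactly six
components, one per region.

For the Levins-Culver model the same pipeline reproduces the classical
coexistence condition:

```python
from stabscape import fixtures, total_boundary
from stabscape.routing import routing_points
from stabscape.connectivity import build_routing_graph

lc = fixtures()["levins_culver"]
arr = total_boundary(lc)          # 7 boundary factors + 4 coordinates = 11
rf, points, _ = routing_points(arr, seed=0, box=[(1e-6, 8)] * 4)
graph = build_routing_graph(rf, points)
print(arr.m, graph.n_components)
```

prints `11 16`: the positive orthant splits into sixteen regions, and
classifying their routing points shows that exactly two carry a locally
asymptotically stable coexistence equilibrium — precisely the regions with
`beta_y > gamma_y` and `beta_z > beta_y (beta_y + gamma_z − gamma_y) / gamma_y`.

2-D slices of the coral model (fixing the coral birth rate `b` and the
mutualist colonization rate `beta_z`) are classified with
`stabscape.landscape.landscape_slice`, or from a shell:

```
stabscape slice coral_reduced.json --fix b=2 --fix beta_z=5/2 \
    --free btilde,dtilde --window 0,10,0,10 --seed 0
```

which writes `regions.csv` labelling each region by its stable
steady-state set (`E_0` total extinction, `E_x` coral only, `E_xy`
mutualist exclusion, `E_xz` pathogen exclusion, `E_co` coexistence, and
two-element sets for bistable regions).

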