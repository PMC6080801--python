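# Methods

`ductnet` models the development of a gland's internal duct system as a
two-phase process on a spatially embedded graph: a noisy growth phase
that builds a loop-rich plexus, and a flux-driven pruning phase that
remodels the plexus into a tree draining to a single exit. This note
records the models, the numerical choices, and what the synthetic data
do and do not establish.

## The network substrate

A sample is a simple undirected graph with 3D node coordinates, per-edge
duct lengths, and a designated root (the exit node). Stored lengths
win over straight-line recomputation because digitised ducts are curved;
lengths absent from the input are filled with Euclidean endpoint
distances. Node IDs are arbitrary positive integers; all matrices use a
dense 0-based index in `node_ids` order. Degree-2 nodes are treated as
duct continuations: `contract_degree2` merges each maximal degree-2
chain between two distinct junctions into one edge carrying the summed
length, preserving total length and the cycle-space dimension
E − N + 1. Closed loops made entirely of degree-2 nodes have no
junctions to merge into and are left intact; a degree-2 loop anchored at
a single junction cannot be contracted without a self-loop and is an
error. Two parallel chains between the same junction pair keep one
interior node so the graph stays simple.

## Network statistics

* **Polygon counts.** Simple cycles of length 3–5 are read off traces
  of adjacency powers: n(C3) = tr(A³)/6,
  n(C4) = [tr(A⁴) − 4·Σᵢ C(dᵢ,2) − 2|E|]/8,
  n(C5) = [tr(A⁵) − 5·Σᵢ A³ᵢᵢ(dᵢ−2) − 30·n(C3)]/10.
  The square-count correction uses the binomial coefficient C(dᵢ, 2):
  with dᵢ² in its place a 4-cycle would count negatively, while the
  binomial form gives exactly 1 (this check is in the test suite, along
  with exhaustive-enumeration equality on random graphs of up to 12
  nodes).
* **Cost and performance.** Cost C = L_tot / L_tot^MST against the
  Euclidean minimum spanning tree of the node cloud (complete-graph MST
  for N ≤ 2000, 15-nearest-neighbour graph with a component-stitching
  fallback above). Performance P = ⟨l⟩/⟨l_MST⟩ with ⟨l⟩ the mean
  weighted shortest-path length over all N² ordered pairs — self-pairs
  included and contributing zero, i.e. the literal 1/N² normalisation;
  the same convention is used for ⟨D⟩, and ⟨D_root⟩ divides by N with
  the root included.
* **Dimension.** For each source node the cumulative count of nodes
  within network distance r is fit as log(count) against log(r + l₀)
  over the window where the count lies between 5 and N/2 (below 5 the
  counts are dominated by discreteness noise, above N/2 by boundary
  saturation). The offset l₀, the median nearest-neighbour spacing,
  anchors the model count(r) ∝ (r + l₀)^dim at the exact point
  count(0) = 1; it removes the small-radius bias of a bare log r fit,
  cancels from the slope at large radii, and keeps the estimate
  invariant under global rescaling of coordinates. All nodes are used
  as sources up to N = 500, then a seeded random subset of 500. The
  estimator is calibrated on references with known limits: 0.97 on a
  200-node chain (1D) and 1.95 on a 20×20 grid (2D), both recomputed in
  the tests and the acceptance script.
* **Randomised counterparts.** Degree-preserving double-edge swaps
  (default 10 attempts per edge), rejecting swaps that create
  self-loops or multi-edges or disconnect the graph; positions are kept
  and rewired edge lengths are recomputed as Euclidean distances.
* **Group comparisons.** Classic equal-variance two-sample two-tailed
  t tests (configurable to Welch), SEM = sd/√n, and a Bonferroni
  threshold alpha/m over the m measures compared.

## Growth model

New lumen nodes are proposed uniformly in the ball of radius
max(d_com) + 0.5 around the network's centre of mass and accepted with
probability ∏ᵢ(1 − exp(−dᵢ)) over existing nodes — proposals on top of
existing lumens are suppressed, which sets the length unit at roughly
one inter-lumen spacing (the +0.5 ball slack is in these units). The
acceptance kernel is written with the decaying exponential; it is the
only reading that is a probability for all distances and penalises
proximity. An accepted node draws M ~ Poisson(λ) and links to M + 1
targets chosen uniformly *without replacement* (links are simple) from
its M + 1 + Δ nearest existing nodes; both counts are capped at the
existing network size. λ = 0.25, Δ = 1 are the defaults (the best-fit
regime for the early plexus); λ = 0, Δ = 0 degenerates to single-link
attachment and always yields a tree.

Initialisation defaults to two nodes joined by a unit edge, which
avoids an undefined first attachment; alternatively a spatially random
binary (dichotomic) tree of 4–100 nodes seeds the model to probe
stereotyped early branching. The root is the first initial node.
Growth is in 3D — the simulated cloud is roughly spherical, so its
network dimension comes out near 3 rather than the ≈2 of the planar
organ; a planar mode exists for comparison. One seeded generator
drives acceptance sampling, the Poisson draw and the pool choice in
that fixed order, so runs are byte-reproducible from (params, seed).

## Diffusion and pruning

The concentration field obeys dφ/dt = −C·L·φ with the combinatorial
Laplacian L = D − A. The Laplacian is deliberately *unweighted*: duct
lengths do not modulate conductance, so the flux field depends only on
topology and boundary placement (a weighted-conductance variant is out
of scope). Boundaries are Dirichlet: φ = 1 at terminals (degree-1
non-root nodes), φ = 0 at the root; the `all_nodes` variant instead
injects a unit source at every non-root node and clamps only the root —
the absolute scale is arbitrary there since only the flux ordering
matters.

The production solver eliminates the clamped nodes and solves the
reduced linear system directly. The forward-Euler scheme
φ(t+Δt) = φ(t) − C·L·φ(t)·Δt (+ source), re-clamping boundaries each
step, is retained as an independent cross-check; it refuses to run if
C·Δt ≥ 1/(2·max degree) and stops when the L1 change per step falls
below tol. Defaults: C = 1, Δt = 1/(C·(2·max degree + 1)),
tol = 1e−10·N, max 10⁷ steps. The two solvers agree to better than
1e−8 (typically 1e−11) on every fixture.

Pruning removes one redundant edge per diffusion re-solve: the
non-bridge edge of smallest flux magnitude, ties broken
lexicographically on the sorted node-ID pair. Each trace event records
the edge, its flux, and the weighted shortest-path distance from its
closer endpoint to the root on the pre-removal network. The loop
terminates exactly when no redundant edge remains, i.e. at a spanning
tree, after E − N + 1 removals. The random baseline removes a
uniformly random redundant edge per step.

## Diameter adaptation

Ducts adapt toward a common wall shear stress:
dd/dt = K[τ − τ_desired]d with τ = 32ηQ/(πd³) from Poiseuille flow, so
the steady state is d = (32ηQ/(πτ_desired))^(1/3) — diameter
proportional to the cube root of flux, equivalently drained basin
proportional to diameter cubed. On pruned trees the per-edge flux
proxy is the drained-basin node count (each node contributing unit
inflow — the exact steady flow under uniform secretion), and both basin
measures (node count and upstream duct length) are computed. The ODE
integrator is explicit Euler (default K = 0.1, Δt = 1e−3, relative
tolerance 1e−10) and converges to the closed form from any positive
start; a two-duct variant with a shared fixed flow reproduces the
competitive collapse of the narrower duct. The basin–diameter exponent
is an ordinary least-squares slope in log–log space with non-positive
pairs dropped; no errors-in-variables correction is applied.

## Synthetic data

No public accession exists for the digitised embryonic samples, so all
inputs are generated:

* **exact fixtures** (triangle, cycles, K4, paths, stars, square
  perimeter, subdivided square, balanced binary trees) carry
  hand-computed statistics for oracle tests;
* **lattice meshes** — jittered triangular-lattice patches, rooted at a
  boundary node, optionally diluted by removing random non-bridge
  edges — provide a loop-rich planar control that is *independent of
  the growth model*, so the metric tests are not circular;
* **plexus stand-ins** wrap the growth model at λ = 0.25, Δ = 1,
  320 nodes (the early-stage regime); **tree stand-ins** use λ = Δ = 0
  (late-stage, polygon-free).

These emulate the statistical structure of the real samples —
planarity (for the lattice), short loops, a designated exit, mean
degree between 2 and 3, a few hundred nodes — but not their anisotropic
outgrowth, duct curvature, or stage-specific absolute sizes. Passing
tests therefore establish the internal correctness and the qualitative
orderings of the methods (flux pruning centres the exit better than
random pruning; pruning proceeds periphery-to-outlet; the cube law is
recoverable under realistic noise), not agreement with any particular
in vivo measurement. `emit_sample_set` writes the two-table-per-sample
file layout so the import path is exercised end to end.

## Problem sizes

Ensemble checks use 320-node networks (the size at which the plexus
stand-in is defined) with 100 seeds for the
pruning-order and flux-vs-random comparisons in the test suite, and 20
seeds in the acceptance script; solver-equivalence and conservation
checks run on 50–80-node networks where exhaustive comparisons are
cheap. These sizes give stable ensemble means (SEMs well inside the
asserted margins) at interactive runtimes.

## Known limitations

* The growth model has no directional cue (no mesenchyme), so simulated
  clouds are spherical; stage-matched anisotropy is out of scope.
* λ and Δ are compared by grid scan and qualitative orderings, not
  fitted by likelihood.
* The unweighted Laplacian ignores duct length and diameter; pruning
  order under a weighted conductance could differ.
* Dimension estimates on small bounded patches are biased low by
  boundary saturation even with the anchored fit; the calibration
  tolerances (±0.15 at 1D, ±0.2 at 2D) reflect this.
* The diameter law is validated on simulated trees; the original
  27-duct in vivo measurement set is not publicly tabulated and is not
  reproduced.
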