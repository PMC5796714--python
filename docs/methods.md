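# Methods

## Model and score

A ranking of a directed graph is an ordered partition of its nodes,
`r: V → {1…R}`.  Agony charges each edge `(u, v)` a penalty
`f_d(r(u) − r(v))` with `f_d(x) = (x+1)^d` for `x ≥ 0` and 0 otherwise,
so forward edges are free, same-class edges cost 1, and backward edges
cost more the further they jump down the order.  The package minimises
`A_d(G, r)` over rankings and reports the hierarchy
`h_d* = 1 − A_d*/m`.  Rank values may be any positive integers when a
ranking is only *evaluated*; optimisers always return canonical
(contiguous, 1-based) rankings, since removing empty classes can never
increase agony.  Self-loops are rejected at graph construction: they
would add a constant `f_d(0) = 1` per loop to every candidate and only
blur comparisons.  Weighted and multi-edges are out of scope.

## Solvers

* **`flow_d1` (exact, d = 1).**  Minimising
  `Σ max(r(u) − r(v) + 1, 0)` over integer labels is the linear-
  programming dual of a minimum-cost circulation.  The constraint matrix
  (`z_e ≥ r_u − r_v + 1`, `z_e ≥ 0`) is a network matrix, hence totally
  unimodular: the LP has an integral optimal vertex, which HiGHS' dual
  simplex returns directly.  The graph is first condensed into strongly
  connected components; inter-component edges can always be oriented
  forward at zero cost by laying the components out in topological
  order, so the LP only runs per non-trivial component and a DAG is
  solved by longest-path layering alone (which is also the
  minimum-class perfect ranking).  Practical scale: a few thousand
  nodes / ~10⁵ edges in minutes on one CPU; the hardest instances are
  near-random graphs with one giant component.
* **`brute` (exact, any d).**  Enumerates every ordered partition
  (ordered Bell numbers; default cap 8 nodes).  Ties are broken to the
  fewest classes, then to the lexicographically smallest rank vector in
  sorted-node order.  This is the validation oracle for every other
  solver.
* **`ilp` (exact, d ≥ 1).**  Integer ranks with one slack per edge and
  the penalty linearised as the maximum of its secant segments; the
  integer-point profile of `f_d` is convex exactly when `d ≥ 1`, so the
  construction is exact there and refuses `d < 1`.  Intended for modest
  sizes where `flow_d1` does not apply (d ≠ 1).
* **`greedy_fas` (heuristic, d = 0).**  The feedback-arc-set case is
  NP-hard; the deterministic greedy linear arrangement (peel sinks and
  sources, otherwise the node of maximal out-minus-in degree) is
  returned with one node per class, taking the better of the order and
  its reversal, which guarantees at most `m/2` backward edges.  Results
  are flagged `optimal=False`.

Among co-optimal rankings the exact solvers apply a greedy
adjacent-class merge pass (accept a merge when the agony is unchanged).
This is a deterministic stand-in for a true minimal-class selection and
can in principle differ from it on degenerate instances; it never
changes the agony value.

## The RSBM generator

`sample` draws each ordered pair independently: probability `p` to the
adjacent higher class, `q` to higher classes beyond it, `s` for every
backward or same-class pair, no self-loops.  Implementation draws a
binomial count per block and places that many distinct pairs uniformly,
which is distributionally identical to per-pair Bernoulli draws and much
faster.  Sampling is driven by `numpy.random.default_rng`; a seed (or
`SeedSequence`) reproduces a graph bit for bit.  Reciprocal cross-class
pairs (2-cycles) can occur, as in any directed SBM with independent
ordered pairs.

The ensemble is used at *desk scale* throughout the tests (N = 128–256,
R = 8–16, class size 16) rather than the thousands of nodes a production
study would use.  These sizes keep the whole suite in minutes while
preserving every qualitative regime (perfect recovery, merging,
inversion, iterated refinement); the quantitative sharpness of the
thresholds improves with N, so empirical switch points at these sizes
are expected to straddle the analytic values, and tests assert regime
properties (monotone class counts, sign of the rank alignment), not
exact switch locations.  What the synthetic tests cannot show: real
networks have degree heterogeneity, non-uniform class sizes and
distance-dependent backward noise, none of which the RSBM emulates.

## First-order theory and conventions

The expected hierarchy of the planted ranking and of merged (`b > 0`),
split (`b < 0`) and inverted candidates is estimated to first order as
`1 − E[A_d]/E[m]`; the neglected covariance corrections vanish as
`N → ∞`.  Within that estimate the block sums are *exact* and validated
against an independent oracle (`expectation_oracle`) that sums
`E[m_ij] · f_d(r̃(i) − r̃(j))` over all block pairs; the test suite pins
closed form vs oracle to 10⁻⁹ across both regimes, all `b`, `d ∈ {1,2}`.

Pair-count convention: the closed forms count `n²` ordered same-class
pairs (`b_0 = Σ n_i²`), while the sampler and the exact expectation
matrix use `n(n−1)` distinct pairs.  The theory module keeps the `n²`
convention, in which the tabulated threshold values are exact; the discrepancy
is `O(1/n)` and the oracle exposes both conventions.

Thresholds returned by `thresholds()` are the closed forms of the
resolution analysis: for `d = 1`, twitter `s_m`, `s_2`, `b*` and military
`s_i`, `s_1`, `s_3^i`, `b^{i,*}`; for `d = 2` the analogous sets (the
twitter interior optimiser `b_2*` has no tractable explicit form and is computed
numerically from the validated closed form); for `d = 0` the
feedback-arc statement (optimal candidate has one node per class, with
estimate ≥ ½ for every valid parameter set).  Several of these have
exact oracle-level meaning, verified symbolically: `s_i` is precisely
where the planted and two-class-inverted estimates tie; the `d = 2`
military `s_{2,1}^0` and `s_{2,2}^i` are precisely the zeros of the
planted and two-class-inverted estimates; `s_{2,3}^i = 3 s_{2,2}^i`
holds identically.  Others are analytic summaries rather than exact
switch points of the integer-candidate family: in particular the
twitter `b*` sits exactly ½ above the true stationary point of the
validated merged-estimate curve, and the integer-b planted→merged
crossover lies somewhat above `s_m`.  For this reason
`optimal_candidate` never evaluates the piecewise formulas: it scans the
whole candidate family (all integer `b`, both orientations, splits down
to singleton classes) with the oracle and returns the argmax.  The
asymptotic scalings — `s_m R² → 6p − 3q`, `s_i R² → 6p`,
`s_{2,1}^0 R³ → 12p` — are asserted numerically in the tests.

Closed candidate forms are restricted to `R = 2^a`, uniform class sizes
and `d ∈ {1, 2}`; everything else (other `d`, non-uniform sizes,
splits) goes through the oracle, which handles them directly.
Partially inverted candidates, observed numerically in the military
regime between the direct and fully inverted phases, are not part of
the analytic family.

## Metrics

The adjusted Rand index is the Hubert–Arabie permutation-model form
computed from the contingency table (cross-validated against
scikit-learn in the tests; scikit-learn is not a runtime dependency).
Because ARI ignores class order — a ranking and its inversion score 1 —
`rank_alignment` complements it with a Kendall correlation of the class
labels: ≈ +1 for order-preserving recovery, ≈ −1 for inversion, 0 (with
a warning) when either ranking is a single class and the correlation is
undefined.

## Iterated agony

`iterated_agony` re-runs the minimiser on the subgraph induced by each
first-pass class and orders nodes by (parent rank, sub-rank).  Defaults:
`depth=2` (a pure two-pass), `min_size=4`, no `stop_h`.  Classes with no
internal edges are left unsplit (every class of an optimally ranked DAG
is of this kind).  The optional `stop_h` rule skips refining a class
whose sub-ranking is confidently binary (hierarchy above `stop_h` with
≤ 2 sub-classes), a guard motivated by the fact that agony happily finds
two classes even in an Erdős–Rényi graph; no universal stopping rule is
attempted.

The refined ranking usually has *lower* global hierarchy than the
(optimal) first pass; the quantity that improves is similarity to the
planted structure.  Measured on the RSBM at desk scale (R = 16, n = 16,
twitter), the two-pass median ARI overtakes the one-pass median once the
backward noise exceeds roughly four times the resolution threshold and
the gain widens with s (e.g. ≈ 0.38 → 0.76 at 8·s_m); just above the
threshold (2–3·s_m) the first pass merges little and the second pass's
spurious layering of sparse, near-DAG single classes outweighs the gain,
so the median ARI there *decreases*.  Both behaviours are asserted in
the test suite at their respective noise levels.

## Numerical choices and edge cases

* LP/MILP solutions are rounded to integers and re-evaluated through the
  exact agony function; a vertex-integrality drift above 10⁻⁶ is an
  error rather than a silent rounding.
* Edgeless graphs: agony 0, hierarchy *undefined* (error) when evaluated
  directly; optimisers report hierarchy 1 for the empty edge set with a
  single class.
* `s > s_max` warns (HierarchyConstraintWarning) instead of raising:
  parameter sweeps deliberately scan up to and past the bound.
* Degenerate thresholds: `b*`-type logarithms with non-positive argument
  return NaN (twitter at small s: no interior merged optimum), and
  `b^{i,*}` is +∞ at s = 0.
* All sweep randomness derives from one master seed via
  `SeedSequence(master, spawn_key=(s_index, replicate))`, so sweeps are
  reproducible cell by cell.

## Known limitations

* The minimal-class tie-break is greedy, not provably minimal.
* `greedy_fas` carries no approximation guarantee beyond `m/2`.
* No polynomial solver for `0 < d < 1` (concave case; brute force only)
  — no algorithm is known — and the `ilp` route for `d > 1` scales
  poorly beyond a few hundred nodes.
* Closed forms do not cover non-power-of-two `R` or non-uniform sizes;
  the oracle does, but thresholds there are not tabulated.
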