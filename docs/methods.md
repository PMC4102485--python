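# Methods

This note documents the model, the numerical choices and the limitations of
`areavenn` in enough detail to audit or extend it.

## Problem statement

Input: seven strictly positive quantities ω(r), one per region interior to
the curves of a 3-Venn diagram, labelled a, b, c, ab, ac, bc, abc (a label
names exactly the curves containing the region). Output: three ellipses
whose seven interior region areas A(r) are directly proportional to ω, plus
a verdict. Proportionality is measured on shares:
regionError(r) = |A(r)/ΣA − ω(r)/Σω| and diagError = max_r regionError(r).
A diagram is *good* iff its topology is a valid 3-Venn arrangement and
diagError ≤ ε with ε = 10⁻⁶. diagError aggregates by the maximum; the mean
was considered and rejected because the maximum reproduces independently
reported error statistics of the circle-restricted mode far better
(aggregating by mean roughly halves typical values).

Quantities are first scaled by 100/min(ω) (so the smallest required region
area is 100 "canvas units"); ω′ denotes the scaled set. All geometry lives
on that scale, which makes the optimizer's default step sizes meaningful
for any input magnitude; diagrams are renormalized only at export. The
scaled values are quantized to 12 significant digits so that proportional
inputs map to bit-identical ω′ — the greedy search is chaotic at the ulp
level and would otherwise return different (equally good) diagrams for
ω and k·ω.

Zero quantities are rejected: the goodness measure and the cost are defined
for seven present regions only.

## Analytic region areas

Each ellipse is (cx, cy, s1, s2, θ) with θ canonically in [0, π); y grows
upward, angles counter-clockwise.

**Boundary intersections.** To intersect two ellipses, one is mapped to the
unit circle by an affine change of frame and the other becomes a conic
Ax² + Bxy + Cy² + Dx + Ey + F. Substituting y² = 1 − x² and isolating the
odd y-terms gives the quartic
(1 − x²)(Bx + E)² = ((A − C)x² + Dx + (C + F))².
Its real roots are taken from the eigenvalues of the companion matrix
(robust where closed-form quartic formulas are ill-conditioned), y is
recovered from the linear relation (or by sign disambiguation when
Bx + E ≈ 0), and each point is polished by 2×2 Newton iteration on the two
implicit equations, then deduplicated at 10⁻⁹ in the normalized frame.
Circle–circle pairs make the quartic a perfect square whose discriminant is
zero in exact arithmetic; the quadratic solver therefore treats
|disc| ≲ 10⁻¹⁰·scale as a double root instead of "no roots". A crossing is
transversal when the sine of the angle between the two gradients exceeds
10⁻⁹; tangential contacts are flagged and count as invalid topology.

**Areas.** Overlap areas are computed by decomposing each overlap boundary
into elliptical arcs (an arc of one curve belongs to the boundary iff its
midpoint is interior to the other curve(s) — overlaps of convex sets are
convex) and summing the exact line integrals ½∫(x dy − y dx). For the arc
of P(t) = c + Q(t) between parameters t₀ < t₁ the integral is
½[s1·s2·(t₁ − t₀) + c × (Q(t₁) − Q(t₀))]. Containment and disjoint cases
are resolved by centre-membership tests. The seven region areas follow by
inclusion–exclusion from the three pairwise overlaps and the triple
overlap; negative round-off up to 10⁻⁹ of the total area is clamped to
zero, anything worse marks the result numerically inconsistent. The exact
per-curve identity A(x) + A(xy) + A(xz) + A(xyz) = π·s1·s2 holds to better
than 10⁻⁹ relative and is asserted in the tests, and all areas are checked
against a rejection-sampling Monte-Carlo oracle.

**Topology validation.** A diagram is a valid 3-Venn arrangement iff every
pair of curves crosses transversally in exactly two points and all seven
regions exceed a positivity floor of 10⁻¹² of the total area (far below the
smallest region share the optimizer must handle, ~3×10⁻⁵). No separate
connectivity search is needed: for three closed convex curves with pairwise
exactly two transversal crossings, the arrangement graph has V = 6 vertices
and E = 12 arcs, so Euler's formula forces exactly F = 8 faces — the outer
face plus at most seven bounded ones. If all seven membership signatures
have positive measure, each must therefore be a single face; a split zone
would need a ninth face. Split zones can only arise through four-point
crossings, which the pair test rejects. The test suite cross-checks this
argument with a grid-sampling connected-component oracle.

## Starting diagram

The optimizer starts from a data-adapted layout of three circles (equal
semi-axes), with rotations 0, π/3 and 2π/3 assigned to curves a, b, c so
later rotation moves cover the angular space. The two curves with the
largest required totals (own region + two pair regions + triple; ties
broken a < b < c) get radii √(total/π) and a separation found by `brentq`
on the closed-form circular lens area, which is strictly decreasing in the
separation — this two-circle sub-diagram is exact. The third circle's
centre moves along L, the bisector of the angle between the tangents to the
first two circles at their upper intersection point, and is placed to match
the required triple-overlap area: the march along L (step r₃/50, both sides
of the intersection point) finds all positions with valid topology, the
discrepancy |A(abc) − ω′(abc)| is bracketed at its grid minima and refined
by bounded Brent/golden-section (the discrepancy is an absolute value and
W-shaped when the target is attainable, so signed bisection does not
apply). When two placements match the target equally well (a shallow and a
deep position always exist in the attainable case), the tie is broken by
the full starting diagram's diagError — the criterion the starting layout
exists to serve. If no valid position exists the centre falls back to the
lens midpoint with a warning and the optimizer recovers.

Tolerances: lens bisection 10⁻¹⁰ relative, third-placement 10⁻⁶ relative,
200 iterations maximum for both.

## Optimization

One iteration sweeps the curves in the fixed order a, b, c; per curve it
explores, in order, eight centre candidates (E, W, N, S, NE, NW, SE, SW
offsets of pγ), eight semi-axis candidates (single axis ±pαβ, both same
sign, both opposite sign), and two rotations (θ ± pθ, renormalized to
[0, π)). Candidate lists are computed once from the curve's state at the
start of each block; each candidate is evaluated against the *current*
diagram and applied immediately if it strictly reduces F6 — greedy,
cumulative acceptance, no best-of-neighbourhood selection. Candidates whose
diagram fails topology validation get an infinite cost sentinel, so every
intermediate diagram is a valid 3-Venn arrangement and the accepted-move
cost trace is strictly decreasing (both are asserted in tests).

Defaults pγ = 10 canvas units, pαβ = 5%, pθ = 2π/3. After an iteration in
which no curve changed its centre / semi-axes / rotation, the corresponding
parameter is halved. The run returns *accurate* as soon as the diagram is
good, and *inaccurate* when pγ, pαβ, pθ are all ≤ 10⁻⁶ (a hard iteration
cap of 2×10⁵ exists but is never reached in practice; observed runs take
tens to a few thousand iterations). In circle mode the semi-axis candidates
reduce to the two uniform scalings and rotation moves are skipped; pθ still
halves every iteration so termination behaves identically.

An inaccurate run hit a local minimum. With reruns enabled the search
restarts from the same starting diagram with all three initial parameters
multiplied by 1.2 (compounding: run k uses defaults × 1.2ᵏ), up to ten
times, returning the first accurate result or the lowest-diagError diagram
of all runs. The whole pipeline contains no randomness: identical
quantities give bit-identical results.

The geometric kernels (intersection, areas, validity, the hill-climb inner
loop) are numba-compiled; one full seven-region evaluation costs ~10 µs,
which is what makes the library-scale evaluation below practical.

## Synthetic data

Two generators emulate the evaluation data:

* **L1, drawable data** — region areas read off random valid ellipse
  triples: centres uniform on [0, 100]², semi-axes uniform on [10, 50],
  rotations uniform on [0, π), rejected until the topology is valid
  (≈12% acceptance), then scaled to total 10⁵ and rounded to positive
  integers. The generating diagram is kept as a drawability certificate
  (its diagError against the rounded item is ≤ 10⁻⁴, the rounding slack).
  The uniform property ranges are this package's choice; they produce
  region shares spanning ~3×10⁻⁵ to ~0.5 of the diagram, i.e. both
  needle-thin and dominant regions.
* **L2, random data** — seven independent integers uniform on [1, 10000];
  drawability unknown a priori.

Per-item seeds derive from the library seed via
`SeedSequence(seed, spawn_key=(index,))`, so libraries are reproducible
across platforms. What the generators do *not* emulate: real gene-list or
cohort data with structured correlations between regions, zero-valued
regions, and the (unpublished) property ranges of the original evaluation —
so rates measured on L1/L2 carry generator-choice uncertainty of a few
percentage points on top of binomial noise, and passing tests show the
method's behaviour under these stated conditions, not on any particular
real dataset.

## Evaluation harness and expected figures

`scripts/acceptance.py` recomputes, from fresh libraries: the first-run
success rate on 200 drawable items (measured ≈99–100%), the success rate
with reruns on 150 uniform-random items (≈83–88%), the circle-restricted
success rate on 100 uniform-random items (0% — circles plateau at
diagError ~10⁻², two orders of magnitude above the threshold), and the
fraction of 1000 starting diagrams with diagError ≤ 0.05 (≈60%). Sample
sizes are chosen so binomial error is small relative to the quantities of
interest while the whole script runs in minutes on one CPU.

## Known limitations

* Three curves only; the cost function's mean-over-regions form would
  generalize, the geometry module would not.
* No exact arithmetic: near-tangent configurations within ~10⁻⁹ are
  classified as degenerate and rejected rather than resolved.
* Some 3-set data admits no accurate convex-curve diagram at all; the
  optimizer then returns its best inaccurate diagram, and no certificate of
  non-drawability is produced.
* Zero quantities are out of scope (the goodness measure presumes seven
  present regions).
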