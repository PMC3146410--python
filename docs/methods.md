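# Methods

## Access model

Demand is represented at census-block granularity: each block is reduced
to its centroid and carries its child population `w_i` as a weight, so a
block of weight `w` behaves identically to `w` children sharing that
centroid. Facilities and block centroids are snapped to the nearest road
network node before routing (ties broken by lowest node id); no
approach-distance term is added for the off-network gap between a
centroid and its snapped node, which is adequate at block granularity
and keeps routing deterministic. Inputs in geographic lat/lon are
rejected — all math is planar Euclidean on projected meters.

Travel speed depends only on road class: 80 km/h (toll), 60 km/h
(national or principal local road), 40 km/h (other), overridable via the
speed table. Travel time on a segment is `(length_m / 1000) / speed × 60`
minutes, summed along the path. The *nearest* facility minimizes network
**distance** by default (time-minimizing assignment is available as
`weight="time"`); every facility is a candidate regardless of region
membership, and this is deliberately not configurable because the CSR
algorithm depends on it. Unreachable block–facility situations raise a
structured error listing the blocks rather than returning infinities,
which would silently corrupt `D`.

A straight-line ("euclidean") mode replaces network routing with planar
distance in km as the access statistic. It exists for fast exploration
and for theoretical arrangement studies; since `D` is scale invariant,
its value in this mode is unaffected by any speed assumption.

## Inequality statistics

The relative mean difference of the weighted access sample is

    D = [ Σ_i Σ_j w_i w_j |x_i − x_j| / W² ] / x̄ ,   W = Σ w_i .

The `W²` (not `W(W−1)`) pair normalization is the adopted definition: it
is the only reading under which `D = 2 × Gini` holds exactly, and the
product-weight generalization makes the block-weighted computation equal
the per-child computation on the exploded sample. `D` is evaluated by an
O(n log n) sorted-gap formula — every gap between adjacent order
statistics is crossed by `C_k (W − C_k)` pairs — which is algebraically
identical to the double sum and returns exactly 0.0 for tied samples.
The Gini coefficient is computed independently via the weighted
Lorenz-curve trapezoid rule, giving a genuine two-route consistency
check (`|D − 2G| < 1e−12` in the tests). `D` is undefined when `x̄ = 0`
(every child co-located with a facility); this raises an explicit error.

Robin Hood (maximum Lorenz gap), Theil T (with `0·log 0 = 0`) and
Atkinson (ε > 0; default 0.5) indices are provided as drop-in
alternative dispersion measures; they are reported only — the
standardized ratio always uses `D` by default. Their rank correlation
with `D` across random samples exceeds 0.9, so substituting them rarely
changes regional orderings.

## CSR standardization

`D̄` is the expectation of `D` when demand is held fixed and the
within-region facilities are uniformly and independently relocated over
the region polygon. Because the observed facility count is conditioned
on, the null is the *binomial* (conditional CSR) process: exactly the
observed number of inside facilities is drawn i.i.d. uniform on the
polygon each replicate, by rejection sampling from the bounding box.
Outside facilities never move, but remain assignment candidates; blocks
outside the region are excluded from `D` in every replicate. After
`n_reps` (default 99) replicates, the simulated values are pooled with
the observed `D` and averaged — `D̄` is the mean of all 100 values, not
of the simulations alone — and `R = D / D̄`.

Relocated facilities are snapped to the nearest network node before
routing, like any other facility; whether an off-road random location
should instead be routed from a perpendicular road projection is an open
modelling question, so the choice is recorded in the result metadata
(`snap_relocated`). Each region uses an independent RNG stream derived
from the user seed and a CRC-32 hash of the region id, so multi-region
runs are order-independent and reproducible bit-for-bit.

Ranking regions uses ascending `R` (and, for comparison, ascending raw
`D`); ties share the lowest rank.

## Synthetic scenarios

The generator emulates the geometric regimes that motivate
standardization, inside a square region with a lattice road network
(optionally with faster principal lines every k-th grid line):

* **regular** — facilities on a centered lattice over uniform demand;
* **clustered** — blocks *and* facilities scattered (σ = extent/20)
  around shared town centers (3 by default), so some towns lack a nearby
  facility; this reproduces the expected ordering that clustered layouts
  are less equitable than regular ones in most seeds;
* **circular** — demand on a ring with one central facility. Ring
  offsets are integer lattice points on a circle of radius 5525 m
  (5525² = 5⁴·13²·17² has 180 representations as a sum of two squares),
  scaled by powers of two to fit the region, so every block is at the
  *same floating-point distance* from the center and the ideal-layout
  limit `D = 0` is exact, not approximate;
* **random** — facilities drawn from CSR itself; feeding such a layout
  back into the standardization is the null-calibration check, under
  which the observed `D` is exchangeable with the simulated ones and the
  mean of `R` across independent studies is ≈ 1 (0.9–1.1 observed over
  50 studies).

Block populations are i.i.d. log-normal (μ = 3, σ = 1 on the log scale,
median ≈ 20 children) rounded to integers ≥ 1 — right-skewed like census
block counts. Defaults: 20 km region side, 11×11 grid, 100 blocks,
10 facilities.

What the generator does **not** emulate: realistic road topology
(capacity, one-way streets, mountains), spatially autocorrelated
population surfaces, or facility-size heterogeneity. Passing tests
therefore validate the *statistical machinery* — routing, the D
identity, the null calibration — not the realism of any particular
prefecture's geography.

## Numerical choices

* Endpoint snapping when building networks uses union-find over pairs
  within `snap_tolerance` (default 0.5 m — absorbs digitization jitter
  without collapsing real intersections); merged nodes take the
  lexicographically smallest coordinate, node ids are assigned in
  coordinate order, so construction is fully deterministic.
* Nearest-node snapping of points resolves exact ties by lowest node id;
  nearest-facility ties go to the lowest facility id.
* Scale invariance of `D` holds exactly under power-of-two rescaling
  (including the speed-doubling invariance of the whole standardization,
  checked bit-for-bit) and to ~1e−9 relative otherwise; replication
  invariance holds to 1e−12.
* Weighted quantiles (box-plot summaries) explode weights conceptually
  into counts and apply linear order-statistic interpolation, matching
  `np.quantile` on the exploded sample for integer weights. Summary
  tables are written at 3 decimal places; JSON sidecars keep full
  precision.
* CSV floats are read with round-trip precision so that write/read
  cycles and re-runs are byte-identical.

## Problem sizes

Default test and reproduction runs use 100-block / 10-facility scenarios
with 99 relocation replicates per region (straight-line mode for the
replicated calibration studies, network mode on 12×12-grid scenarios),
chosen so a complete run of the suite plus the reproduction script
finishes in well under a minute on one CPU while keeping Monte Carlo
error on mean-`R` summaries near 0.02.

## Known limitations

* Car-only travel at legal speed limits; no congestion, slope, turn
  restrictions, one-way streets or multi-modal transport.
* Nearest-facility choice only — no gravity or floating-catchment
  utilization models, no capacity constraints, no activity-space travel
  behavior.
* Facilities are relocated strictly within the region boundary; the
  effect of allowing relocation beyond it is not examined.
* `D̄` is a Monte Carlo estimate: with 99 replicates its standard error
  is a few percent of `D̄`, which propagates into `R`. Increase
  `n_reps` when small `R` differences matter.
* No hypothesis-test p-values are produced from the Monte Carlo
  distribution; the method reports the ratio only.
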