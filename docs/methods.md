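# Methods

## The model

`anatomap` derives network connectivity, connection lengths and conduction
delays from the geometry of neuronal sheets.  A **layer** is a 2-manifold
mesh (triangles and quads) embedded in 3D, millimetre units, with a
per-face-corner **UV chart** — the flattened-surface coordinate system that
stands in for local anatomical axes (e.g., septo-temporal and
proximo-distal in the hippocampal formation).  Somata, synapses and
projection waypoints all live on layers; a position is a triangle index
plus barycentric coordinates, from which 3D position and chart position
derive.

A projection is a **mapping chain**: an ordered list of hops carrying each
neuron from its soma layer, through optional intermediate layers, onto the
**synaptic layer** (SL) where the pre- and post-synaptic sides meet.  Four
operators implement a hop:

* *topological* — identical mesh structure, same triangle + barycentric
  coordinates re-anchored on the target (deformed/mirrored copies);
* *normal* — intersection of the smoothly interpolated surface-normal
  line with the target, both directions, nearest hit by |t| with ties
  toward the positive side; a miss means the neuron projects nowhere,
  which is how sub-populations are masked;
* *euclidean* — globally closest point on the target surface (exact
  closed-form point–triangle distance; spatial pruning never changes the
  result; ties resolve to the lowest triangle index);
* *random* — area-uniform position on the target, independent of the query.

Normals are angle-weighted vertex normals interpolated barycentrically;
flat face normals would make the projection discontinuous across edges.

## Connectivity model and samplers

Each neuron that reached the SL at chart position `z_n` carries a
non-negative kernel `w(z | z_n)` over SL chart space — the reach of its
arbor and the density of synapse formation.  The probability of a synapse
between pre `i` and post `j` at position `z` is proportional to the product
`w_pre(z | z_i) · w_post(z | z_j)`.  Kernels are unnormalized with peak 1
(normalization happens per neuron over the sampling domain), so thresholds
read as fractions of the peak.  Built-ins: anisotropic 2D Gaussian and 1D
Gaussian along one chart axis; new kernels register by name.  Kernel
widths are in chart units; on non-isometric charts a fixed chart width is
a varying metric width, and the `param_fn` hook converts a metric reach to
local chart units from the neuron's own position (used on the cone strips).

Two samplers draw synapses per pre neuron (outgoing budget; an
incoming-budget mode swaps roles):

* **Exact**: the full discrete joint over (bin, post) with weight
  `w_pre(c_b) · w_post_j(c_b)` at every bin center `c_b`, normalized and
  sampled directly.  Cost per pre neuron is bins × posts.
* **Bin-grid (fast)**: the SL chart's bounding rectangle is rastered into
  `cu × cv` bins.  Each post neuron registers in every bin where its
  kernel at the bin center is at least `p0` of its peak; weights are
  stored.  Per pre neuron, bins below `p1` of its peak are skipped, the
  remaining bins drawn with probability ∝ `w_pre(c_b)` times the bin's
  total stored post weight, and the partner inside the drawn bin with
  probability ∝ its stored weight (Bayes' rule with a uniform prior over
  posts).  Including the per-bin total — the evidence term — makes the
  accelerated sampler target exactly the same joint as the exact sampler
  when `p0 = p1 = 0`; dropping it would bias bins where the summed post
  weight is unusually large or small.  This equivalence is a tested
  contract (two-sample chi-square on the (pre, post, bin) joint; total
  variation of the edge marginal < 0.02 at 5×10⁴ draws).

Kernels are evaluated at bin centers, not integrated over bins; a warning
fires when a kernel is narrower than ~3 bins.  Synapse positions are
uniform within the drawn bin, realized on the surface through the chart;
off-chart draws retry within the bin (default 10 times) and then drop the
synapse with a warning — preferable to nearest-neighbour snapping, which
would distort the distribution near chart boundaries.  Defaults:
`p0 = p1 = 10⁻³`, 16 × 16 bins.  Fixed seed ⇒ bit-identical connectome
including record order.

## Connection lengths and delays

Every chain hop contributes an inter-layer leg in one of three modes:
`euclidean` (chord to the image), `normal` (length along the normal line),
`jump` (distance to the closest point of the next layer, a lower bound).
A `UV` affix adds the along-surface distance on the layer just reached —
the straight chart segment discretized into steps of at most half the
smallest UV edge (flat-sheet error < 10⁻⁹, curved-fixture error < 0.5%),
each sample lifted to 3D, chord lengths summed.  Because traversal
continues from the arrival point, that term is zero on intermediate layers
and is realized on the SL from the entry point to the synapse.  The final
hop always ends at the synapse: a plain-euclidean final hop measures the
chord straight to the synapse; normal/jump final hops measure their leg to
the entry point and add the residual entry→synapse chord.  All lengths are
lower bounds — real arbors meander, these trajectories do not.

Delays are `rate × length` with `rate = 4.36 ms/mm`, the measured
conduction latency of rat CA3 axons, optionally multiplied by a lognormal
factor with mean 1 and configurable coefficient of variation
(`jitter_cv`, default 0) to emulate developmental variability; the factor
is strictly positive so delays never go negative.

## Analysis surface

Populations are ordered along a chart axis (stable sort, ties by id) and
indices normalized to [0, 1] so differently sized populations compare; the
**index difference** of a synapse is normalized pre index minus normalized
post index, in [−1, 1].  Spread is its standard deviation, overall or per
band of pre neurons; uncertainties use a delete-one-pre-neuron jackknife
because the draws of one pre neuron are correlated.  Distance
distributions compare via an exact two-sample KS statistic with the
asymptotic Kolmogorov p-value, reported as computed.

## Spiking validation

A minimal Izhikevich network (`v' = 0.04v² + 5v + 140 − u + I`,
`u' = a(bv − u)`, spike at 30 mV, reset `v → c`, `u += d`; defaults
a = 0.02, b = 0.2, c = −65 mV, d = 8) integrated by forward Euler at
dt = 0.1 ms (two half-steps on v for stability).  Synapses are
instantaneous voltage increments: a spike adds its weight (mV) to the
target's `v` after its conduction delay, via a ring-buffer event queue
quantized to dt (delays must be ≥ dt).  The stimulus delivers independent
per-neuron Poisson-timed pulses (default 1 event/ms, 50 mV, first 10 ms)
added directly to `v` — one reading of an under-specified noisy current
drive; any construction that reliably fires the input population gives the
same ordering conclusions downstream.  Forward Euler at this dt keeps
first-spike times and inter-spike intervals stable under dt-halving,
though absolute spike phases drift ~0.3% per period over long tonic runs.

## Synthetic geometry and the bundled surrogates

All tests run on generated fixtures with closed-form areas (planar sheets;
tube strips = partial cylinders; cone strips = frustum strips whose
septo-temporal circumference grows from a proximal radius `r_p` to a
distal radius `r_d`; normal-offset, mirrored and midpoint-subdivided
copies).  Generators are deterministic, and analytic band areas/arc
lengths give the statistical tests exact expectations.

Three bundled surrogates stand in for traced anatomy:

* **Spread comparison** — cone strip (r 0.15 → 1.05 mm, length 2 mm, half
  arc) vs tube strip at the cone's mean radius; 2000 pre + 2000 post
  neurons placed uniformly per unit area, 20 synapses per pre, identical
  Gaussian kernels whose septo-temporal reach is fixed at 0.2 mm (metric)
  via the position hook.  On the cone, uniform areal density concentrates
  neurons distally while a fixed metric reach spans a v-dependent chart
  fraction, so the index-difference spread both exceeds the tube's overall
  (Cauchy–Schwarz: E[1/L]·E[L] ≥ 1 for circumference L(v)) and varies
  monotonically across proximal–distal bands; on the tube it is flat.
* **Distance comparison** — two frustum segments (CA3-like, CA1-like)
  sharing one offset SL; 250 pre × 22 synapses = 5500 connections whose
  pre kernel reaches 0.30 (chart) along the proximal-distal axis.  The
  same connectome is measured with UV-affixed and with straight-chord
  modes; UV totals dominate chord totals synapse-by-synapse (triangle
  inequality plus path ≥ chord) and the distributions separate far beyond
  the p < 10⁻⁵⁰ level.
* **Hippocampal loop** — six parallel 1 mm² sheets (sEC, DG, CA3, CA1,
  Sub, dEC) at z = 0, 2, 4, 6, 7.5, 10 mm (dEC deliberately farther from
  CA1 than Sub, mirroring the longer output pathway), seven projections
  through mid-gap SLs with normal mapping and chord distances; population
  sizes 110/1200/250/390/285/330 (experimental ratios scaled by 10⁻³),
  literature weights (9/5/4/5/4/4/4 mV), synapse counts from the
  per-post in-degrees (38, 15, 60, 85, 15; the two dEC projections reuse
  15).  Delays at 4.36 ms/mm yield strictly increasing first-spike
  latencies around the loop (≈0.2, 9, 18, 27, 34, 45 ms at these gaps).

What the surrogates do **not** emulate: traced meshes with irregular,
non-developable charts (our strip charts are near-isometric by
construction, so chart-unit kernels behave metrically); realistic
entorhinal→DG perforant-path geometry (the loop's inter-layer gaps are a
rough average, as in the source setup); inhomogeneous neuron density
beyond the explicit density-map mechanism; axonal/dendritic branching
morphology (out of scope by design).  Passing tests therefore demonstrate
the correctness of the machinery and the direction of the morphology
effects, not quantitative agreement with any specific traced anatomy.

## Numerical choices

* Quads triangulate deterministically as (0,1,2)/(0,2,3).
* Chart lookup uses a uniform grid over UV bounding boxes; containment
  tolerance 10⁻⁹ barycentric; overlapping charts resolve to the lowest
  triangle; degenerate UV triangles are skipped.
* Neuron placement: faces ∝ area (× a per-face density upper bound from
  the grid cells overlapping the face when a density map is active),
  square-root barycentric construction inside the face, rejection against
  the local bilinear density — exactly density-proportional placement.
* Closest-point queries prune candidates with a KD-tree vertex bound vs
  per-triangle bounding spheres; pruning is provably conservative and
  tested equal to exhaustive search.
* Line–mesh intersection: Möller–Trumbore with 10⁻⁹ barycentric slack;
  among hits, minimal |t| wins, positive t preferred on ties (10⁻¹⁵
  relative tie window), then lowest triangle index.
* KS p-values use `kolmogorov(√(n_a n_b/(n_a+n_b)) · D)`; below double
  precision they underflow to 0 and are reported as such.
* CSV dialect is fixed (header `pre_id,post_id,distance_mm,delay_ms`,
  9 significant digits, decimal point, LF) so reproducibility can be
  asserted byte-for-byte.

## Known limitations

* Neurons and synapses are confined to the 2-manifold; there is no
  volumetric offset model.
* Kernel σ in chart units is only metrically meaningful on (near-)
  isometric charts; the metric hook is the escape hatch, not a general
  solution.
* The bin-grid sampler evaluates kernels at bin centers; kernels much
  narrower than a bin degrade to point masses (warned).
* The spiking module is a validation harness (no inhibition, plasticity,
  conductances, or sub-dt delays), not a general simulator.
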