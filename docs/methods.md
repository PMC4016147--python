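# Methods

This note documents the estimators, conventions and parameter defaults in
`roostnet`, the design choices made where several reasonable conventions
exist, and what the synthetic-data tests do and do not demonstrate.

## Networks

**Construction.** The relocation table (one row per bat-day-roost) defines
an unweighted bipartite graph: an edge joins bat *b* and roost *r* iff *b*
was relocated at *r* at least once.  Repeated use is deliberately not
encoded as edge weight: with uneven per-bat tracking durations, weights
would mostly measure observation effort.  Single-mode projections connect
two bats (or two roosts) iff they share at least one opposite-mode
neighbour; isolates are retained because they enter density and
centralization denominators and component counts.  Analyses are
year-stratified throughout — bats tracked in two years appear as distinct
nodes in each annual network — because the tracked subsets of the colony
differ between years.

**Metrics.**

- Density: single-mode 2L/(n(n−1)); two-mode L/(n_bats·n_roosts).
  Consistency identities (density = mean degree/(n−1); two-mode density =
  roost mean degree / n_bats) are tested exactly.
- Degree centralization: single-mode Freeman, Σᵢ(d_max−dᵢ)/((n−1)(n−2)).
  Two-mode: the same numerator over all nodes of both sets, normalized by
  the maximum attainable in a bipartite graph of identical dimensions.
  That maximum is a star whose hub sits in the smaller set:
  max(n₁,n₂)·(n₁+n₂−2), since Σᵢ(d_max−dᵢ) = (n₁+n₂)d_max − 2L is maximized
  at d_max = max(n₁,n₂) with the minimal L realizing it.  The formula is
  confirmed against exhaustive enumeration of all bipartite graphs at
  small dimensions in the test suite rather than hard-coded per case.
- Clustering: single-mode, the mean Watts–Strogatz local coefficient over
  nodes with degree ≥ 2 (degree-1 nodes are excluded from the average, not
  counted as zero — the standard convention).  Two-mode, the closed-4-path
  coefficient: a 4-path i–a–j–b–k (i, j, k in the focal set, a ≠ b
  opposite) is closed when the ends i and k share at least one
  opposite-set neighbour; the coefficient is closed / total.  The focal
  set defaults to roosts for the roost network.  A projection-based
  alternative (single-mode clustering of the projection) remains available
  by composing `project` with `clustering`.
- Modularity: leading-eigenvector community detection, implemented
  directly.  For each candidate community the generalized modularity
  matrix B⁽g⁾ = B_g − diag(row sums of B_g) is formed (B = A − kkᵀ/2m);
  the community is split along the sign pattern of the leading
  eigenvector, the bisection is fine-tuned by Kernighan–Lin style
  single-node sweeps (each pass flips every node once in greedy gain
  order and keeps the best prefix), and the split is accepted only if it
  increases Q = Σ_c(e_cc − a_c²).  Rows of B⁽g⁾ sum to zero, so a leading
  eigenvalue ≤ 0 means no sign vector can increase Q and the community is
  indivisible.  `max_communities=2` restricts the recursion to a single
  bisection.  On graphs small enough for brute force (≤ 8 nodes) the
  single-bisection result matches the exhaustive maximum-modularity
  bipartition, and the full recursion recovers the two-clique split of the
  standard two-K4-bridge benchmark (Q = 0.4231).
- Mean shortest path: average geodesic distance over unordered pairs in
  the same component; disconnected pairs are excluded and their count is
  reported.  Observed colony networks are nearly connected, so exclusion
  is rare but explicit.
- Homophily: Newman nominal assortativity r = (Σe_ii − Σa_i b_i)/(1 − Σa_i b_i)
  on the edge mixing matrix over a categorical attribute (age class),
  computed from a sorted-class mixing matrix for bit-reproducibility and
  cross-checked against networkx.  Undefined (error) when edge endpoints
  carry fewer than two classes.

Reported tables round to two decimals; full precision stays on the report
objects.

## Null models

Observed metrics are compared with an ensemble of Erdős–Rényi random
graphs with the same node counts (bipartite G(n₁, n₂, p) for two-mode
networks) and constant link probability p.  The study-derived constant is
the observed network's density, which is the default p; a fixed p can be
configured.  N = 500 draws by default; all metrics of one suite share the
same seeded draw sequence.  A draw on which a metric is undefined (e.g.
homophily when a sparse null draw's edges span one class) is resampled for
that metric, keeping N constant; resample counts are reported.

P-values use the add-one Monte Carlo estimator: with b exceedances (ties
counted as exceedances), the tail p is (b+1)/(N+1) ∈ [1/(N+1), 1], so p
can never be zero and the floor at N = 500 is 1/501 ≈ 0.002.  The reported
value is the smaller tail's p with its direction (">" above the null bulk,
"<" below, "=" when the tails coincide).  A doubled two-tailed variant
(min(1, 2·p_tail)) is available via `two_tailed=True`; the calibration
test uses it and confirms the rejection rate at nominal 0.05 stays at or
below nominal (within binomial error) when the observed metric is drawn
from the same ER law as the nulls.  Both conventions are recorded in the
result metadata because the directional single-tail format is what the
reporting tables use.

## Removal simulations

Run on the single-mode roost projection (degree there, not bipartite
degree, defines "most central").  Random removal: for each proportion on
a grid (default 0.05 steps from 0 to 0.70, leaving 30 % of roosts),
⌊p·n⌋ uniformly chosen nodes are deleted and connected components counted
(an isolated node is a component; the empty graph has 0), over 1 000
seeded replicates; the curve reports mean ± SE.  Targeted removal deletes
the k most degree-central nodes, ties broken deterministically by smallest
node id and recorded.  Exactness anchors: a complete graph never
fragments; a 6-path with one node removed has exactly 5/3 expected
components; removing a star's hub leaves n−1 components.

## Utilization distributions

**Segmentation.** Successive fixes of one bat form segments; a segment
spanning > 60 min (T_max) is unusable for bridging, one covering < 50 m
(L_min) is resting, the rest are bridges.  All three constants are
configurable; time is in minutes, distance in meters, area in hectares.

**Plug-in diffusion.** Each interior fix flanked by non-unusable segments
is modelled, under the Brownian-bridge interpolation of its two
neighbours, as bivariate normal around the linear interpolation with
per-coordinate variance 2·D·T·p(1−p) (T the flanking duration, p the
relative time).  The leave-one-out log-likelihood is maximized in closed
form, D̂ = Σᵢ(dᵢ²/wᵢ)/(4n) with wᵢ = Tᵢpᵢ(1−pᵢ), and verified against a
1-D grid search of the same likelihood.

**Biased random bridges.** A bridge segment deposits Gaussian mass at
interpolated positions (12 substeps by default) with per-coordinate
variance h_min² + 2·D·T·p(1−p), i.e. the bridge variance floored by the
minimum smoothing parameter h_min = 88 m; resting segments deposit h_min
kernels at their endpoint fixes; segments are weighted by duration.  If
every gap exceeds T_max the fixes fall back to equally weighted point
kernels.  Kernels are cell-integrated (1-D normal CDF differences, outer
product) on a regular grid; the estimator errors out if less than 99.9 %
of the mass lands on the grid ("extend grid").  A fine time-quadrature
oracle reproduces the 3-fix toy UD within 1 % total variation.

**Weighted fixed kernels.** Colony-level UDs are weight-normalized
mixtures of isotropic bivariate normal kernels.  The reference bandwidth
for weighted points is h = σ·n_eff^(−1/6) with σ² the mean of the weighted
coordinate variances and n_eff = (Σw)²/Σw² the effective sample size; the
convention is recorded in the UD metadata.  Roosting UDs weight roost
locations by days used by tagged bats; the pooled foraging UD is
unweighted (weighting is a roost-use concept).  The roosting-area
centroid is the roost-day-weighted mean location, which coincides with
the kernel UD mean for symmetric kernels.

**Grid.** Default cell 30 m; extent is the bounding box of the inputs
buffered by 4 bandwidths (so ≤ ~0.01 % of any kernel's mass is clipped).
Halving the cell size moves BA, UDOI and isopleth areas of smooth UDs by
< 2 % (tested), which is what justifies the default.

**Isopleths and overlap.** The level-α isopleth is the smallest
highest-density cell set holding ≥ α of the mass; its area is cell count ×
cell area.  UDOI = A_overlap · Σ(f_a f_b ΔA), with A_overlap the
intersection area of the two 95 % isopleths and f the 95 %-truncated,
renormalized densities (the untruncated integral is available via
`truncate=False`).  Identical uniform UDs give exactly 1; concentrated
joint use gives > 1; disjoint UDs give 0.  BA = Σ√(f_a f_b)ΔA ∈ [0, 1],
computed on the full UDs.  Closed-form anchors: equal-σ Gaussians at
separation d have BA = exp(−d²/8σ²); a Gaussian's 95 % isopleth area is
π σ² χ²₂(0.95).  The foraging association network joins dyads with UDOI
strictly > 1, among bats with ≥ 40 fixes (the eligibility the UD estimate
needs); a dyad is "socially close" when its geodesic in the social network
is strictly below that network's mean shortest path.

## Telemetry summaries

The switch interval is the mean length in days of same-roost runs of
consecutive tracked days; a tracking gap (> 1 day between relocations)
breaks a run even at an unchanged roost, and the number of gap-broken runs
is reported.  Because "average interval" can mean the mean of per-bat
means or the mean over all runs, both aggregations are emitted.  The
observation-bias check is a log-link Poisson GLM of roosts used on
relocation count (statsmodels IRLS, verified against an independent Newton
optimizer), reporting the Wald 95 % CI for the slope, deviance explained
D² = (null − residual)/null deviance, and adjusted
D² = 1 − [(n−1)/(n−p)](1−D²); a constant response defines D² = 0.  The
roost-use/emergence comparison is a Pearson correlation with two-sided
t-test p, refusing zero-variance inputs.

## Synthetic colony generator

The generator emulates one colony-year of maternity-colony telemetry and
is the package's test bed; its defaults are the study conditions for all
simulation-based checks.

- **Roost preferences.** A colony-level backbone puts Zipf weights
  j^(−c) on roost ranks (c = `primary_concentration`); each bat's
  preference vector is Dirichlet(s·n_roosts·backbone) with
  s = `preference_strength` (6.0).  c = 0 makes roosts exchangeable;
  c → ∞ is a point mass on the shared primary roost; intermediate values
  give one primary plus bat-specific secondaries.  The default c = 1.0
  reproduces the diffuse-use regime of a tracked Indiana bat colony's
  first study year (switching every ~3.3 days, ~3 roosts per bat, two-mode
  centralization ~0.45); c ≈ 1.4 reproduces the concentrated second year.
- **Roosting.** Each bat has a contiguous tracking window (truncated
  normal length, mean 9.3 d, SD 5.0 d); each day it stays put with
  probability 1 − `daily_switch_prob` (default 0.3) or redraws from its
  preference vector (a redraw may repeat the roost, so the realized
  switching rate is slightly below the nominal one).
- **Foraging.** Bat-specific centres are drawn around a small number of
  shared foraging patches (2 by default, jitter 75 m) that belong to the
  landscape and persist across colony-years under a separate
  `landscape_seed`; nightly fixes follow a discrete correlated random walk
  with mean reversion 0.5 toward the centre and step SD 390 m, 8 fixes per
  6-hour night, whole-minute jittered timestamps ≥ 3 min apart.  These
  values give ~395 ha individual BRB ranges and ~40–45 % of dyads with
  UDOI > 1, matching the reported scale of Indiana bat maternity-colony
  foraging.  Only the UD machinery is under test, not the movement
  process itself.
- **Exit counts.** On sampled roost-nights (15 % of roost-nights) the
  count is the number of tagged occupants plus the untagged colony
  (default 60 bats) distributed multinomially by the backbone; sampled
  nights with no occupants report zero, as in real monitoring.
- **Seeding.** One global seed spawns named substreams (layout,
  preferences, roosting, foraging, exit counts), so toggling one stage
  never changes another, and all outputs are bit-identical across runs
  and processes.

What passing synthetic tests show — and what they do not.  The generator
reproduces the marginal structure the analyses consume (preference
concentration, switching tempo, tracking effort, shared foraging space,
emergence-count scale).  It does not model roost ephemerality, weather or
parasite-driven switching, triangulation error, transmitter failure beyond
window length, age-class assortment (so homophily fluctuates around
zero), or habitat geometry; agreement of the pipeline with closed forms
and oracles on these data therefore validates the estimators, not any
ecological claim about a real colony.

## Degenerate inputs and tie rules

Empty relocation tables, edgeless graphs for modularity, single-class
homophily, all-zero kernel weights, zero-variance correlations, and
too-small grids all raise errors with specific messages rather than
returning silent defaults; no-4-path two-mode clustering and
no-degree-≥2-node single-mode clustering return 0 with a warning.
Isopleth cell ranking, targeted-removal ties and KL sweeps break ties
deterministically (stable sorts, smallest id).  Monte Carlo p-values count
ties as exceedances.

## Problem sizes

Simulation-based tests and the reproduction script use the study's actual
scale (21–25 bats, 17–33 roosts, 500 null draws, 1 000 removal
replicates) with 30 m grids; the full reproduction run takes well under a
minute on one CPU, and the complete test suite a little over one.
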