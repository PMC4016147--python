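# roostnet

Roosting/social network and foraging space-use analysis for fission–fusion
bat maternity colonies.

Many temperate bats form summer maternity colonies that spread across a set
of day-roosts (typically one heavily used "primary" roost plus many
secondary roosts) and reshuffle membership through frequent roost
switching.  Radio-telemetry of such a colony yields three tables: daily
diurnal roost relocations per tagged bat, nightly foraging fixes, and dusk
emergence counts at roosts.  `roostnet` turns those tables into the
standard analysis chain used in network ecology and movement ecology:

- **Two-mode network analysis.** Bats and roosts are the two node sets of an
  unweighted bipartite graph *B* with an edge (b, r) whenever bat *b* used
  roost *r*.  The single-mode projection of the bat nodes is the colony's
  *social network*; the projection of the roost nodes is the *roost network*.
  Metrics: density (two-mode L/(n₁n₂); single-mode 2L/(n(n−1))), mean
  degree, degree centralization (Freeman Σᵢ(d_max−dᵢ)/((n−1)(n−2));
  two-mode variant normalized by the bipartite star maximum), clustering
  (Watts–Strogatz mean local coefficient; two-mode closed-4-path
  coefficient), mean geodesic distance, leading-eigenvector modularity Q,
  and nominal assortativity ("homophily") by age class.
- **Monte Carlo null models.** Observed metrics are compared with 500
  Erdős–Rényi graphs of matched dimensions and link probability (default:
  the observed density), with add-one permutation p-values
  p = (b+1)/(N+1) reported with the direction of difference; the smallest
  attainable p with N = 500 is 1/501 ≈ 0.002.
- **Removal simulations.** Colony robustness to roost loss: random node
  removal on the roost projection (1 000 replicates per proportion removed,
  up to 70 %; mean ± SE component counts) and targeted removal of the most
  degree-central roost.
- **Utilization distributions and overlap.** Individual foraging UDs by
  biased random bridges (plug-in diffusion estimate; 60 min / 50 m
  segment rules; 88 m minimum smoothing), colony roosting/foraging UDs by
  weighted bivariate-normal fixed kernels, 95 % isopleth areas, UDOI and
  Bhattacharyya affinity between UDs, and the UDOI > 1 foraging
  association network for bats with ≥ 40 fixes.
- **Telemetry summaries.** Roost-switching intervals, roosts per bat,
  a Poisson GLM check that roosts-used is not an artifact of tracking
  effort (with adjusted D²), and the correlation between tagged-bat roost
  use and maximum emergence counts.

A synthetic colony generator (`roostnet.synthetic`) reproduces the
statistical structure of such telemetry — Zipf/Dirichlet roost
preferences with a shared primary roost, Markovian daily switching,
correlated-random-walk foraging around shared hotspots, and emergence
counts including an untagged colony fraction — so the whole chain runs and
is tested without any field data.

## Worked example

```python
from roostnet import (ColonyConfig, ERConfig, generate_colony, build_bipartite,
                      project, roost_network_report, social_network_report,
                      run_null_suite, metrics as M)
from roostnet.networks import attach_node_attributes

colony = generate_colony(ColonyConfig(seed=1))       # one colony-year
bnet = build_bipartite(colony.relocations)
print(f"{bnet.n_bats} bats, {bnet.n_roosts} roosts, {bnet.n_edges} edges")

row = roost_network_report(bnet).as_row()
social = project(bnet, "bats")
attach_node_attributes(social, colony.bats, "bat_id", ["age_class"])
srow = social_network_report(social).as_row()

results = run_null_suite(
    bnet,
    {"clustering": M.clustering_two_mode,
     "degree_centralization": M.degree_centralization_two_mode},
    ERConfig(n_sims=500, seed=1),
)
for r in results:
    print(f"{r.metric_name}: observed {r.observed:.2f} ({r.direction}, {r.p_value:.3f})")
```

prints

```
21 bats, 20 roosts, 63 edges
clustering: observed 0.54 (>, 0.333)
degree_centralization: observed 0.50 (>, 0.002)
```

Here 21 tagged bats used 20 distinct roosts.  The roost network's two-mode
degree centralization (0.50) is larger than in every one of the 500
density-matched random bipartite graphs (add-one p = 1/501 ≈ 0.002): roost
use concentrates on a primary roost far more than chance coincident use
would produce.  Its two-mode clustering (0.54) is higher than the null
median but not significantly so at this density.  The metric rows
(`row`, `srow`) carry the remaining columns — density, mean degree,
modularity Q, mean shortest path and age-class homophily — rounded to two
decimals for reporting, with full precision kept on the report objects.

The full year-stratified pipeline (networks, nulls, removal, spatial
overlap, summaries, cross-year space-use comparison) runs from one config:

```python
from roostnet import PipelineConfig, run_pipeline
cfg = PipelineConfig(years={"2009": ColonyConfig(seed=1)}, outdir="out")
report = run_pipeline(cfg)
```

or from the shell: `roostnet simulate --outdir colony && roostnet networks
colony --outdir out` (subcommands: simulate, networks, nulls, removal,
summaries, all).

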