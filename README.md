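# pigsna — proximity-based social network analysis of group-housed pigs

Modern precision-livestock systems track every pig in a pen continuously:
an overhead camera plus a deep-learning stack emits, frame by frame, each
animal's ear-tag identity, posture (standing / lying / sitting) and the XY
coordinates of its shoulder and rump in metres. `pigsna` turns those
tracking streams into **weighted social networks** and quantifies the pen's
social structure at three levels:

* **group** — Freeman centralization of degree, closeness, betweenness and
  eigenvector centrality; network density; Newman modularity;
* **subgroup** — Louvain communities, maximal cliques (count and largest
  size), clique co-membership matrices, and Mantel permutation tests that
  compare co-membership structure between days and growing periods;
* **individual** — degree / closeness / betweenness / eigenvector
  centrality and the local clustering coefficient per animal.

Because commercial farm tracking data are rarely shareable, the package
includes a first-class **agent-based pen simulator** with planted
affiliative structure, so every stage of the pipeline can be exercised,
calibrated and validated against a known ground truth.

## The model in brief

**Interactions.** Two pigs interact when both are *standing* inside the
daily 06:00–18:00 observation window and their shoulders are within
**0.5 m** (Euclidean). A maximal interval satisfying this at every common
sample is a *proximity bout*; dropout gaps up to 10 s are bridged. A bout
contributes to the network only if its duration **exceeds the mean bout
duration of its pen-day** — brief incidental encounters are filtered out.
For each pen and day an undirected network is built over the full roster,
with edge weight = summed seconds of qualifying proximity per dyad.

**Group centralization** follows Freeman's index

```
C = Σᵢ (C_max − Cᵢ) / max possible Σ (C_max − Cᵢ)
```

where the denominator is evaluated on the most centralized configuration
with the same number of nodes (the star graph; the one-hot vector for
eigenvector centrality), so C = 1 for a perfect star and C = 0 when all
animals are equally central.

**Modularity** is Newman's weighted Q, `Σ_c [W_c/W − (S_c/2W)²]`, maximized
by seeded multi-restart Louvain with a final local-move refinement.

**Period contrasts.** Traits are compared between the early and late
growing periods with a linear mixed model
`value ~ period + pen_size + (1|pen) + (1|day)` (REML), reporting
least-square means and the period-contrast p-value.

**Coordinate quality** is audited the way a tracking system should be:
body length (shoulder–rump distance) must be repeatable within animal
(CV of roughly 0.10–0.18 under realistic keypoint noise) and must not vary
between the inner and outer pen areas by more than ~0.15 m, which would
indicate camera distortion.

## Worked example

Simulate one 12 h day of an 18-pig pen with two planted friend groups and
strong attraction (affinity 0.9), then run the analysis:

```python
from pigsna import (AnalysisConfig, SimConfig, simulate_pen, filter_window,
                    daily_networks, louvain_partition, maximal_cliques)
from pigsna.network_metrics import group_traits

sim = SimConfig(n_pigs=18, n_days=1, affinity=0.9, rng_seed=1)
records, truth = simulate_pen(sim)         # 155,520 tracking records
cfg = AnalysisConfig()
standing = filter_window(records, cfg)     # 40,880 standing, in-window
nets, raw, qual = daily_networks(standing, sim.roster(), cfg, "early")
net = nets[1]                              # day-1 contact network
part = louvain_partition(net, seed=1)
print(group_traits(net, part.labels))
print(part.communities())
print(maximal_cliques(net).count, maximal_cliques(net).largest_size)
```

Output (abridged):

```
degree_centralization         0.257
closeness_centralization      0.381
betweenness_centralization    0.038
eigenvector_centralization    0.197
density                       0.771
modularity                    0.391
communities: 2  ->  {pig01..pig09} and {pig10..pig18}
maximal cliques: 18, largest clique: 11
```

4,811 raw bouts were detected, of which 1,935 were sustained longer than
the pen-day average and entered the network. Louvain recovers the two
planted groups exactly (modularity 0.39); the moderate degree
centralization (0.26) says no single pig dominates the contact structure.

The same flow is available from a shell:

```bash
pigsna run --seed 1 --outdir out --pens 2       # full two-period pipeline
pigsna simulate --seed 1 --outdir out           # tracking CSV + ground truth
pigsna validate out/tracking_pen1.csv           # coordinate-quality report
```

`pigsna run` writes tracking CSVs, bout tables, GraphML networks, trait
tables, community/clique/co-membership CSVs, Mantel results, the mixed-model
period comparison and a reproducibility manifest.

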