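# Methods

This note records the modelling choices behind `pigsna`: what each stage
computes, the defaults and why, what the simulator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## 1. Tracking records and filtering

A record is one animal at one timestamp: pen, ear-tag ID, calendar day,
seconds since midnight, posture ∈ {standing, lying, sitting}, and shoulder
and rump XY keypoints in metres from the pen's top-left corner. The CSV
schema is fixed (`pen_id,animal_id,day,t,posture,shoulder_x,shoulder_y,
rump_x,rump_y`); floats are written with shortest round-tripping
representation and read back with `float_precision="round_trip"`, so
write → read → write is byte-identical.

Only *standing* animals inside the half-open daily window
[06:00, 18:00) enter the network analysis. Standing-only filtering
restricts the analysis to active behaviour, where proximity reflects a
choice by both animals rather than a shared resting spot. The window is
implemented as pure arithmetic on `t` (`21600 ≤ t < 64800`), making the
filter idempotent and order-preserving.

Coordinates up to 0.2 m outside the pen are clamped to the wall and
logged (keypoint noise of a few centimetres is expected); anything further
out is rejected with the offending line numbers. Unknown ear tags are
dropped with a warning rather than rejected, since transient
mis-identifications should not abort a batch run.

## 2. Proximity bouts and contact networks

Two animals are in proximity when their shoulder–shoulder Euclidean
distance is **≤ 0.5 m** (the threshold is inclusive). Because real
trackers are not perfectly synchronized, each dyad's samples are paired by
nearest timestamp within half a sampling interval (default 5 s sampling →
2.5 s pairing tolerance).

A *bout* is a maximal interval over which every common sample qualifies.
Two rules govern interruptions:

* a common sample whose distance exceeds the threshold always ends the
  bout — the animals demonstrably separated;
* a *missing-data* gap (no common sample at all, e.g. a tracker dropout)
  of at most `gap_tolerance_s` (default 10 s = two missed samples) is
  bridged. Setting `gap_tolerance_s = 0` disables merging entirely.

Bout duration runs from the first to the last qualifying sample, so a
single isolated sample has zero duration and is discarded; no sub-sample
durations are invented.

A bout enters the network only if its duration is **strictly greater than
the mean raw-bout duration of its pen-day**. The mean is pooled over all
bouts of the pen-day by default; a per-dyad-then-across-dyads mean is
available via `mean_bout_mode="per_dyad"` (the pooled form is the default
because per-dyad means are undefined for dyads that never interact). With
zero bouts the threshold is 0 and everything qualifies (logged).

The daily contact network is undirected, spans the full roster (isolated
animals stay as nodes), has zero diagonal, and edge weight = summed
qualifying proximity seconds. Total edge weight always equals total
qualifying bout seconds (a conservation property the pipeline manifest
checks on every run).

## 3. Network traits

Conventions (each switchable per call):

| trait | graph used | notes |
|---|---|---|
| degree centrality | binarized | incident edges / (n−1) |
| closeness | weighted | shortest paths on lengths 1/weight; networkx's reachable-set scaling for disconnected graphs; a literal "sum of direct connections" strength variant exists as `closeness_mode="strength"` |
| betweenness | weighted | lengths 1/weight, normalized by (n−1)(n−2)/2 |
| eigenvector | weighted | leading eigenvector of the weight matrix, scaled to max 1 |
| clustering coefficient | binarized | closed neighbour pairs / k(k−1)/2; 0 for degree < 2 |
| density | binarized | edges / C(n, 2) |
| centralization | binarized | see below |

**Centralization** is Σᵢ(C_max − Cᵢ) divided by the same sum on the most
centralized graph of equal n. Rather than hard-coding per-metric closed
forms, the denominator is computed *empirically* on the star graph (the
maximizer for degree, closeness and betweenness) with the same centrality
routine — one rule for all kinds, verified against the closed forms in the
tests. For eigenvector centrality the maximizing configuration is the
one-hot score vector, giving denominator n − 1 under max-normalization.
Centralizations are computed on the binarized graph by default
(`weighted=True` switches to the weighted centralities), since the
binarized form is the common convention for group-level summaries and is
invariant to uniform weight rescaling.

**Modularity** is Newman's weighted Q = Σ_c [W_c/W − (S_c/2W)²] with W the
total edge weight, W_c the within-community weight and S_c the community
strength sum; Q of an edgeless network is defined as 0.

Per-period summaries are the mean and SD of the per-day values.

## 4. Subgroups

**Communities.** Louvain on the weighted graph. The greedy local-move
order is randomized, so the implementation (a) restarts the networkx
Louvain routine 8 times from seeds derived deterministically from the call
seed and keeps the highest-Q partition, and (b) finishes with a
deterministic single-node local-move refinement to convergence (nodes in
sorted order, best strictly-improving move). On exhaustive small-graph
benchmarks this lands within a few percent of the true optimum; the
reported modularity is always recomputed with the package's own Q so the
two can never disagree. Edgeless networks yield singleton communities with
a warning.

**Cliques.** Maximal cliques of the binarized graph via Bron–Kerbosch with
pivoting (`networkx.find_cliques`), canonically ordered, with
`min_clique_size = 2` by default — an isolated animal is not a "clique".
The **co-membership matrix** counts, per dyad, the maximal cliques
containing both animals; its diagonal is each animal's own clique count.
A positive off-diagonal entry implies the edge exists.

**Mantel tests** compare two co-membership matrices: r is the Pearson
correlation of the off-diagonal upper triangles (Spearman available), and
p = (1 + #{r_perm ≥ r_obs}) / (perms + 1) under joint row+column
permutation of the second matrix. The default alternative is one-sided
("greater"), matching the directional question of whether co-membership
structure *persists*; two-sided is available. Constant matrices are
flagged rather than failed. Cross-period comparisons are emitted both for
matched day pairs (1↔1, 2↔2, 3↔3) and for all nine cross pairs, since
either pairing is defensible.

## 5. Period comparison

Each trait is modelled as `value ~ period + pen_size + (1|pen) + (1|day)`,
fitted by REML with statsmodels `MixedLM` using variance components inside
a single grouping to express the two *crossed* random factors (a nested
day-within-period variant is not currently implemented; day levels are
shared across periods). Group-level traits are modelled at pen-day grain;
individual traits can be passed at animal-day grain with the same model.

Pragmatic degeneracy handling, in order: a constant pen-size covariate is
dropped (it is collinear with the intercept); a random factor whose
estimated variance collapses to ~0, or whose fit fails to converge or
yields non-finite covariances, is dropped with a note — the model then
reduces toward OLS. The period contrast uses a t reference with
df = n − p_fixed − Σ(levels − 1) over the retained random factors, a
deliberately simple Satterthwaite-style surrogate: under the simulated
null (6 pens × 3 days × 2 periods) its empirical size at α = 0.05 is
statistically indistinguishable from nominal (the acceptance suite checks
the 99% binomial band over 500 replicates). Least-square means hold the
covariate at its grand mean.

## 6. The pen simulator

The simulator generates what the tracking system would have produced for
a pen with known social structure. Per 12 h window:

* **Posture**: each pig alternates standing/lying via a two-state Markov
  chain. The exit rate from standing is 1/(10 min mean standing bout); the
  entry rate is solved so the stationary standing fraction equals the
  pig's target standing time. Targets are drawn per pig from
  N(170.28, 52.21²) minutes/day (clipped to [20, 700]) — the calibration
  constants of commercial growing pigs under camera monitoring.
* **Movement**: the tracked point is the *body centre*. Standing pigs take
  Gaussian steps (sd 0.10 m per 5 s) plus a drift of magnitude
  `affinity × step_sd` toward the centroid of the other standing members
  of their planted group; lying pigs are stationary. Centres reflect off a
  half-body-length inset box, which guarantees both keypoints stay inside
  the pen for any heading.
* **Keypoints**: shoulder and rump sit half a body length fore/aft of the
  centre along the heading (the direction of the last displacement). Body
  lengths are drawn per pig, mean 0.60 m, CV 0.10 across pigs — a growing
  pig's shoulder–rump distance. Independent Gaussian noise (sd 0.05 m) is
  added to every coordinate and the result clamped to the pen.

With these defaults the within-animal body-length CV is ≈ √2·0.05/0.60 ≈
0.12 (delta method), inside the 0.10–0.18 range a well-calibrated tracker
exhibits, and the inner/outer pen-area body-length contrast is ≈ 0 because
the noise is location-independent — together these make the simulator a
usable testbed for the validation module.

Default pen: 6 m × 3 m, 18 pigs, two equal planted groups, affinity 0.6,
5 s sampling, 3 days. All randomness flows from one `rng_seed`; identical
seeds give byte-identical CSVs.

**What the simulator does not emulate** — and hence what passing tests do
*not* establish about farm data: no identity switches or detection
dropouts (tracking is perfect); no posture-classification errors; no
resource hotspots (feeders/drinkers) or diurnal activity rhythm;
attraction is constant and group-structured rather than dyadic and
dynamic; no growth between periods. Planted-structure recovery therefore
demonstrates the *pipeline's* correctness, not the detectability of social
preference in any particular barn. Simulated networks are also denser
than typical commercial-pen contact networks, because the attraction model
keeps group mates within the proximity threshold for much of their
standing time; `affinity` and `step_sd_m` are the dials that govern this.

The deterministic `make_toy_records` builder scripts exact trajectories
(piecewise-linear waypoints, no noise) for hand-verifiable fixtures; the
test suite's seven-bout scenario (gap-merge case, exactly-0.5 m case,
posture-filter case) is built with it.

## 7. Validation module

Body length = shoulder–rump Euclidean distance. The repeatability CV is
sd/mean per animal, averaged per pen; a variance-components repeatability
(e.g. intra-class correlation) would be a reasonable alternative estimator
and is intentionally left out of scope. "Outer" pen area = body midpoint
within 0.5 m of any wall, "inner" otherwise — the split is not standardized
anywhere, so it is defined geometrically here and exposed as a parameter.
The area effect is |mean inner − mean outer| per animal with the pen
maximum reported; animals seen in only one area are skipped with a warning.

## 8. Problem sizes and numerical notes

* Tests and the acceptance script run full 12 h pen-days (8,640 samples ×
  16–19 pigs) for simulation-based checks, and 2 simulated pens × 2
  periods × 3 days for the end-to-end pipeline — sizes chosen so the whole
  suite completes in a few minutes on one CPU while matching the study's
  per-day data volume exactly.
* Exhaustive oracles (subset cliques, all set partitions for modularity,
  full 4! Mantel enumeration) are restricted to n ≤ 12, n ≤ 10 and n = 4
  respectively, where enumeration is tractable.
* Eigenvector centrality uses a dense symmetric eigendecomposition
  (pens have ≤ 19 animals; no need for power iteration).
* Mantel p-values use the add-one rule, so p ≥ 1/(perms + 1) always.
* Ties in Louvain are broken by seeded visiting order; community labels
  are canonicalized by each community's smallest member, so partitions are
  comparable across runs.
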