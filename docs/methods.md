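# Methods

## The network model

Metabolism is represented as a directed bipartite graph. Metabolite nodes
and reaction nodes form the two partitions; a reactant metabolite links into
its reaction and a reaction links out to each product. A reversible
reaction defines links in both directions for every participant, so a
reversible reaction node has degree 2 × (number of participants) and an
irreversible one exactly (number of participants), after duplicate-link
suppression (a metabolite occurring twice on one side contributes one link;
stoichiometry remains in the reaction payload). Links carry no weights:
reaction mass conversion and flux are condition-specific and hard to
measure, so topology alone is compared across definitions.

Two orthogonal simplifications are exposed as parameters:

**Compartmentalization.** The compartmental build gives one node per
(metabolite, compartment) pair occurring in an included reaction and keeps
transport reactions — reactions that move a chemically unchanged metabolite
between compartments. The consensus (non-compartmental) build keeps one
node per chemical entity, drops pure transport reactions (meaningless
without compartments), and merges chemically redundant reactions — identical
multiset of (metabolite, role, stoichiometry) after dropping compartments
and identical reversibility — into a single consensus node whose process,
gene, and reference lists are unions. Reactions that both transport and
convert ("both") are kept by default; a flag excludes them too.

**Metabolite exclusion.** Named metabolites (hub lists) are removed as
nodes, and any metabolite whose total link count exceeds a degree threshold
(default 50) is removed as well. Degrees are evaluated on the network
*before* any exclusion so list-based and threshold-based exclusion commute.
Reaction payloads keep their complete participant information, so exclusion
changes topology, not chemistry. After exclusion the largest *weakly*
connected component is kept (strong connectivity would discard most of any
directed metabolic graph).

Reaction inclusion filters: a reaction passes a compartment filter if all
its participant compartments are in the allowed set, and a process filter if
at least one of its processes is allowed. Everything is tie-broken
lexicographically by identifier, so every build and query is deterministic.

## Model curation

Reactions are classified by comparing the stoichiometry-weighted multisets
of reactant and product metabolite identities: a difference means chemical
conversion; the same metabolite appearing on both sides in different
compartments means transport; both can hold at once. Identity is compared
on consensus identifiers, not formulas, since consensus identifiers already
encode chemistry.

Flux-simulation artifacts — exchange with the model's boundary compartment,
biomass accumulation, protein assembly/degradation — provide no context for
intracellular measurements and are removed by a configurable filter:
reactions touching designated boundary compartments, plus reactions whose
name or identifier matches user-supplied case-insensitive patterns. No
canonical pattern set exists across model releases, so the patterns ship in
a visible configuration file (`config/example.yaml`) rather than in code.
After removal, metabolites participating in no remaining reaction are
dropped; the filter is idempotent.

Transport reactions inherit membership in processes that span at least two
compartments and share at least one metabolite and one compartment with
them, so pathway annotations survive the compartmental build.

Curation summaries report entity counts and reference coverage — metabolites
with an HMDB or PubChem reference, reactions with a gene or enzyme
reference — as percentages rounded to two decimals.

## Graph metric conventions

All network-level metrics are single-mode: computed relative to one
bipartite set (metabolites by default). The conventions below matter
because several variants exist in the literature; each is validated against
brute-force enumeration oracles on fixtures of ≤ 20 nodes.

- **Density** = size / (2·|M|·|R|), the directed bipartite maximum.
- **Degree centrality** of a node = (in + out degree) / (2 × opposite-set
  size).
- **Betweenness** sums, over ordered pairs of distinct nodes, the fraction
  of directed shortest paths through the node; normalization divides by
  twice the published bipartite (affiliation-network) maximum for the
  node's set — the factor 2 converts the unordered-pair maximum to ordered
  pairs. The exact denominators are written in `metrics.py`.
- **Centralization** of already-normalized centralities is
  Σ(c_max − c_i)/(n − 1), reaching 1.0 for the {1, 0, …, 0} star pattern.
  With centralities bounded by 1 this is the attainable maximum, and it
  keeps the statistic comparable across network sizes.
- **Clustering** of node u is the mean Jaccard overlap of neighborhoods
  |N(u)∩N(v)|/|N(u)∪N(v)| over u's second-order neighbors v on the
  undirected view; nodes without second-order neighbors score 0.
- **Mean path length** averages directed shortest-path lengths (in links,
  so same-set distances are even and ≥ 2) over reachable ordered same-set
  pairs only; the unreachable-pair count is reported alongside rather than
  being folded into the mean.
- **Small-world σ** = (C/C_rand)/(L/L_rand), where C_rand and L_rand are
  means over a seeded ensemble (default 10 replicates) of uniformly random
  directed bipartite graphs matched in *both* part sizes and link count.
  Matching only node counts would make C_rand and L_rand incomparable.
  A degenerate ensemble (C_rand = 0) raises rather than returning infinity.
- **Assortativity** is the Pearson degree correlation over links of the
  directed single-mode projection (u → w iff some reaction receives a link
  from u and sends one to w; self-loops excluded). A zero-variance degree
  sequence (e.g., a pure cycle) returns 0 with an explicit `defined=False`
  flag instead of NaN.
- **Influence ranks**: metabolites are ranked separately by degree and
  betweenness centrality (1 = most central, ties averaged); the total rank
  is the mean of the two.

## Measurement processing

Analyte tables are relative-quantification data: only within-sample ratios
are meaningful, so each sample is normalized to its total signal over
measured analytes (idempotent and scale-invariant). Before normalization,
analytes measured in less than a configurable fraction (default 0.5) of the
samples of either group are dropped, and redundant analytes mapping to one
metabolite are collapsed to the one with the smallest index of dispersion
(sample variance over mean, n−1 denominator) in the control group; a zero
control mean flags the dispersion infinite and deprioritizes the analyte,
and exact ties break lexicographically.

Group comparison, case over control: paired designs take per-pair
log2(case/control) ratios (incomplete pairs dropped per analyte), report
their mean, and test them against zero with a two-sided dependent-samples
t-test; unpaired designs report log2(mean_case/mean_control) with a
two-sided independent t-test, equal-variance by default and Welch by flag.
Non-positive values entering a log exclude the analyte with a log entry.
Degenerate zero-variance tests map to p = 1 when the mean difference is
zero. Raw p-values are used downstream; Benjamini–Hochberg adjustment is
available as an opt-in extra column.

Analytes match model metabolites through normalized PubChem identifiers
(trimmed, leading zeros and CID prefixes removed). An analyte intersecting
several metabolites goes to an ambiguity report instead of being assigned —
matching judgment calls cannot be automated, so ambiguity is surfaced, not
resolved.

## Module detection

Each measured metabolite gets z = Φ⁻¹(1 − p), clamped below at −10 so
p → 1 stays finite; a subnetwork with k scored members aggregates them as
z_A = Σzᵢ/√k. From every scored metabolite, a greedy hill-climb repeatedly
adds the scored metabolite within the configured link depth (default 2) of
the current cluster that most increases z_A, together with the
lexicographically smallest shortest connecting path (whose reactions join as
unscored connectors), until no addition improves the score. Candidates are
ranked by z_A; for each Jaccard overlap threshold (defaults 0.25, 0.50,
0.75) up to 25 clusters are emitted, suppressing candidates overlapping an
already-emitted cluster beyond the threshold.

This deterministic greedy search deliberately replaces the simulated
annealing of classic active-module tools: at the scale of curated metabolic
networks it recovers planted signal reliably (see the seeded recovery test)
while making outputs exactly reproducible. The optional background
calibration of z_A against random same-size node sets is not applied by
default. Greedy growth is a heuristic: it can absorb a moderately scored
neighbor that annealing would reject, so emitted clusters are "raw" and a
mechanical filter prioritizes the interpretable ones — at most 3 reactions,
each reaction's in-cluster metabolites mostly measured, and both
accumulation (log2FC > 0) and depletion (log2FC < 0) present.

## Synthetic data

The toy-model generator emulates the structural motifs that matter to the
pipeline — linear and cyclical pathways, identical pathway copies in
multiple compartments joined by transport reactions, and planted hub
metabolites of chosen degree — with PubChem references attached so analyte
matching works end to end. Named fixtures pin exact topologies: `toy4`
(four-metabolite irreversible cycle), `toyhub` (the cycle plus a degree-4
hub), `toycomp` (the cycle duplicated in two compartments with two
transports).

Simulated studies draw per-analyte baselines on the log2 scale
(mean 10, spread 2) and per-measurement noise σ = 0.25 log2 units, with
case-group signals multiplied by 2^effect; paired mode shares one baseline
per (analyte, pair) with pair spread 1.0 log2 units, so the pair ratio
isolates effect + noise. At these defaults a dependent t-test with n = 10
pairs has essentially full power for a 2-fold effect (effect/SD of the pair
ratio ≈ 2.8), which is what the sign-recovery property exercises. All
generators are pure functions of their specification including the seed.

What the generator does *not* emulate: realistic genome-scale topology
(degree distributions, scale), missing-not-at-random detection limits,
heteroscedastic platform noise, correlated analytes, or batch effects.
Passing tests demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artifact of real studies.

## Problem sizes in the test suite

Simulation-backed checks run at deliberately small scale: σ calibration
uses five 30+30-node random networks against 50-replicate ensembles; the
t-test size check uses 1,000 analytes at n = 10 per group; planted-module
recovery uses 20 seeded replicates on a 60-metabolite network; oracle
equivalence covers all fixtures up to 20 nodes. These sizes give stable
statistics while keeping the whole suite around ten seconds.

## Known limitations

- Genome-scale curated networks (and therefore their published absolute
  metric values) require external model archives; the package validates its
  formulas on printed dimensions and on oracle-checked fixtures instead.
- The SBML reader is a strict structural subset (compartments, species,
  reactions, reversibility, stoichiometry, identifier URIs); kinetic laws,
  rules, events, and groups are ignored with a notice.
- Hub lists are identifiers, not chemistry: they must be adapted to each
  model's namespace.
- The greedy module search provides no significance calibration by
  default; scores are meaningful relatively, within one annotated network.
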