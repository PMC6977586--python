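"""Single-mode graph metrics for directional bipartite metabolic networks.

All network-level metrics here are "single-mode": they are computed relative
to one bipartite node set (metabolites or reactions) at a time.  Normalized
metrics compare against the maximum possible for a directed bipartite
network of the same dimensions ("comparison to maximum"), and the
small-world coefficient compares against an ensemble of random directed
bipartite networks matched in part sizes and link count ("comparison to
random").

Conventions, documented because the field offers several:

* Density denominator is ``2 * |M| * |R|``, the number of possible directed
  metabolite<->reaction links.
* Degree centrality of a node is ``(in + out degree) / (2 * |opposite set|)``.
* Raw betweenness sums over ordered pairs of distinct nodes the fraction of
  directed shortest paths through the node; it is normalized by twice the
  published bipartite maximum (Borgatti & Everett affiliation-network
  denominators; the factor 2 converts the undirected unordered-pair maximum
  to ordered pairs).  With ``n`` nodes in the node's own set and ``m`` in
  the opposite set, the undirected maximum for that set is
  ``[m^2 (s+1)^2 + m (s+1)(2t-s-1) - t (2s-t+3)] / 2`` with
  ``s, t = divmod(n-1, m)``.
* Centralization of already-normalized centralities ``c_i`` is
  ``sum(c_max - c_i) / (n - 1)``, which reaches 1.0 for the {1, 0, ..., 0}
  star pattern.
* Single-mode clustering of node ``u`` is the mean Jaccard overlap
  ``|N(u) & N(v)| / |N(u) | N(v)|`` over its second-order neighbors ``v``
  (undirected view); nodes without second-order neighbors score 0.
* Mean path length counts links (same-set distances are even) over all
  reachable ordered same-set pairs; the unreachable-pair count is reported
  alongside.
* Degree assortativity is Pearson degree correlation over the links of the
  directed single-mode projection (u -> w iff some reaction receives a link
  from u and sends one to w); a zero-variance degree sequence yields 0 with
  ``defined=False`` instead of NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import METABOLITE, REACTION, MetabolicNetwork, NetworkSpec


def _mode_sets(network: MetabolicNetwork, mode: str) -> tuple[list[str], list[str]]:
    if mode == METABOLITE:
        return network.metabolite_nodes, network.reaction_nodes
    if mode == REACTION:
        return network.reaction_nodes, network.metabolite_nodes
    raise ValueError(f"mode must be 'metabolite' or 'reaction', got {mode!r}")


def bipartite_density(n_metabolites: int, n_reactions: int, size: int) -> float:
    """Directed bipartite density: ``size / (2 * |M| * |R|)``."""
    if n_metabolites <= 0 or n_reactions <= 0:
        raise ValueError("density undefined for an empty bipartite set")
    return size / (2.0 * n_metabolites * n_reactions)


def degree_centrality(network: MetabolicNetwork, mode: str) -> pd.Series:
    """Total degree over the directed-link maximum ``2 * |opposite set|``."""
    own, opposite = _mode_sets(network, mode)
    if not opposite:
        raise ValueError("degree centrality undefined with an empty opposite set")
    maximum = 2.0 * len(opposite)
    graph = network.graph
    values = {
        node: (graph.in_degree(node) + graph.out_degree(node)) / maximum
        for node in own
    }
    return pd.Series(values, name="degree_centrality").sort_index()


def _betweenness_maximum(n_own: int, n_opposite: int) -> float:
    """Published bipartite betweenness maximum for nodes of one set."""
    s, t = divmod(n_own - 1, n_opposite)
    m = n_opposite
    return (
        (m**2) * (s + 1) ** 2 + m * (s + 1) * (2 * t - s - 1) - t * (2 * s - t + 3)
    ) / 2.0


def betweenness_centrality(network: MetabolicNetwork, mode: str) -> pd.Series:
    """Directed shortest-path betweenness normalized by the bipartite maximum."""
    own, opposite = _mode_sets(network, mode)
    raw = nx.betweenness_centrality(network.graph, normalized=False, weight=None)
    if len(own) > 2 and opposite:
        denominator = 2.0 * _betweenness_maximum(len(own), len(opposite))
    else:
        denominator = 1.0
    values = {node: raw[node] / denominator if denominator else 0.0 for node in own}
    return pd.Series(values, name="betweenness_centrality").sort_index()


def raw_betweenness(network: MetabolicNetwork) -> dict[str, float]:
    """Unnormalized directed betweenness for every node (oracle hook)."""
    return nx.betweenness_centrality(network.graph, normalized=False, weight=None)


def centralization(centralities) -> float:
    """Freeman-style deficit sum ``sum(c_max - c_i) / (n - 1)``.

    Expects centralities already normalized into [0, 1]; the denominator
    ``n - 1`` makes the {1, 0, ..., 0} star pattern score exactly 1.
    """
    values = np.asarray(list(centralities), dtype=float)
    if values.size < 2:
        raise ValueError("centralization requires at least two nodes")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("centralities must be normalized into [0, 1]")
    return float((values.max() - values).sum() / (values.size - 1))


def bipartite_clustering(network: MetabolicNetwork, mode: str) -> pd.Series:
    """Mean pairwise Jaccard coefficient over second-order neighbors."""
    own, _ = _mode_sets(network, mode)
    graph = network.undirected()
    values: dict[str, float] = {}
    for node in own:
        first = set(graph[node])
        second = {v for u in first for v in graph[u]} - {node}
        if not second:
            values[node] = 0.0
            continue
        coefficients = []
        for other in second:
            other_first = set(graph[other])
            union = first | other_first
            coefficients.append(len(first & other_first) / len(union))
        values[node] = float(np.mean(coefficients))
    return pd.Series(values, name="cluster_coefficient").sort_index()


@dataclass
class PathSummary:
    """Mean directed shortest-path length over reachable same-set pairs."""

    mean_length: float
    reachable_pairs: int
    unreachable_pairs: int


def mean_path_length(network: MetabolicNetwork, mode: str) -> PathSummary:
    """Mean shortest directed path length between same-set ordered pairs.

    Lengths count links, so same-set distances in a bipartite network are
    even and at least 2.  Pairs with no directed path are excluded from the
    mean and counted separately.
    """
    own, _ = _mode_sets(network, mode)
    if network.order == 0:
        raise ValueError("mean path length undefined on an empty network")
    own_set = set(own)
    total = 0
    reachable = 0
    for source in own:
        lengths = nx.single_source_shortest_path_length(network.graph, source)
        for target, distance in lengths.items():
            if target != source and target in own_set:
                total += distance
                reachable += 1
    possible = len(own) * (len(own) - 1)
    if reachable == 0:
        raise ValueError("no reachable same-set pair; mean path length undefined")
    return PathSummary(total / reachable, reachable, possible - reachable)


def random_bipartite(
    n_metabolites: int, n_reactions: int, size: int, seed: int
) -> MetabolicNetwork:
    """Uniformly sample ``size`` distinct directed metabolite<->reaction links."""
    possible = 2 * n_metabolites * n_reactions
    if size > possible:
        raise ValueError(f"size {size} exceeds the {possible} possible links")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(possible, size=size, replace=False)
    width = max(len(str(n_metabolites)), len(str(n_reactions)))
    graph = nx.DiGraph()
    for i in range(n_metabolites):
        graph.add_node(f"m{i:0{width}d}", kind=METABOLITE, name=f"m{i}")
    for j in range(n_reactions):
        graph.add_node(f"r{j:0{width}d}", kind=REACTION, name=f"r{j}")
    for index in sorted(int(x) for x in chosen):
        direction, rest = divmod(index, n_metabolites * n_reactions)
        i, j = divmod(rest, n_reactions)
        met, rxn = f"m{i:0{width}d}", f"r{j:0{width}d}"
        if direction == 0:
            graph.add_edge(met, rxn, role="reactant")
        else:
            graph.add_edge(rxn, met, role="product")
    return MetabolicNetwork(graph, NetworkSpec(), provenance=f"random(seed={seed})")


def sigma_small_world(
    network: MetabolicNetwork, mode: str, replicates: int = 10, seed: int = 0
) -> float:
    """Small-world coefficient ``(C/C_rand) / (L/L_rand)`` vs matched randoms.

    The ensemble matches both part sizes and link count of the observed
    network; ``C_rand`` and ``L_rand`` are means over ``replicates`` seeded
    draws.  Values far above 1 indicate modular structure with short paths.
    """
    own, opposite = _mode_sets(network, mode)
    observed_c = float(bipartite_clustering(network, mode).mean())
    observed_l = mean_path_length(network, mode).mean_length
    n_met = len(network.metabolite_nodes)
    n_rxn = len(network.reaction_nodes)
    c_values, l_values = [], []
    for replicate in range(replicates):
        random_net = random_bipartite(n_met, n_rxn, network.size, seed + replicate)
        c_values.append(float(bipartite_clustering(random_net, mode).mean()))
        try:
            l_values.append(mean_path_length(random_net, mode).mean_length)
        except ValueError:
            continue
    c_rand = float(np.mean(c_values))
    if c_rand == 0 or not l_values:
        raise ValueError(
            "degenerate random ensemble (no clustering or no reachable pairs); "
            "increase replicates or network size"
        )
    l_rand = float(np.mean(l_values))
    return (observed_c / c_rand) / (observed_l / l_rand)


def project_single_mode(network: MetabolicNetwork, mode: str) -> nx.DiGraph:
    """Directed unipartite projection: u -> w iff a reaction takes u in and sends w out."""
    own, _ = _mode_sets(network, mode)
    own_set = set(own)
    graph = network.graph
    projection = nx.DiGraph()
    projection.add_nodes_from(own)
    for u in own:
        for via in graph.successors(u):
            for w in graph.successors(via):
                if w in own_set and w != u:
                    projection.add_edge(u, w)
    return projection


@dataclass
class AssortativityResult:
    value: float
    defined: bool = True


def assortativity(network: MetabolicNetwork, mode: str) -> AssortativityResult:
    """Pearson degree assortativity of the directed single-mode projection."""
    projection = project_single_mode(network, mode)
    if projection.number_of_edges() < 2:
        raise ValueError("assortativity undefined with fewer than 2 projected links")
    with np.errstate(invalid="ignore", divide="ignore"):
        value = nx.degree_assortativity_coefficient(projection)
    if not np.isfinite(value):
        # constant degree sequence: correlation has zero variance
        return AssortativityResult(0.0, defined=False)
    return AssortativityResult(float(value), defined=True)


# ---------------------------------------------------------------------------
# Node tables, ranks, and the consolidated report


def centrality_table(network: MetabolicNetwork, mode: str) -> pd.DataFrame:
    """Per-node degree/betweenness centrality and cluster coefficient."""
    return pd.DataFrame(
        {
            "degree_centrality": degree_centrality(network, mode),
            "betweenness_centrality": betweenness_centrality(network, mode),
            "cluster_coefficient": bipartite_clustering(network, mode),
        }
    )


def rank_metabolites(centralities: pd.DataFrame) -> pd.DataFrame:
    """Rank nodes by degree and betweenness influence (1 = most central).

    Ties receive the average rank; ``total_rank`` is the mean of the two
    ranks, and the output is sorted by total rank then identifier.
    """
    if centralities.empty:
        raise ValueError("cannot rank an empty centrality table")
    degree_rank = rankdata(-centralities["degree_centrality"], method="average")
    between_rank = rankdata(-centralities["betweenness_centrality"], method="average")
    out = pd.DataFrame(
        {
            "degree_rank": degree_rank,
            "betweenness_rank": between_rank,
            "total_rank": (degree_rank + between_rank) / 2.0,
        },
        index=centralities.index,
    )
    # stable sort: ascending total rank, ties by identifier
    return out.sort_index().sort_values("total_rank", kind="mergesort")


#: Column order mirrors the standard network-properties table layout.
REPORT_COLUMNS = [
    "order_total",
    "order_metabolites",
    "order_reactions",
    "size",
    "density",
    "centralization_degree",
    "centralization_betweenness",
    "mean_path_length",
    "mean_cluster_coefficient",
    "sigma",
    "assortativity",
]


@dataclass
class MetricsReport:
    """One row of network-level metrics plus the per-node table behind it."""

    order_total: int
    order_metabolites: int
    order_reactions: int
    size: int
    density: float
    centralization_degree: float
    centralization_betweenness: float
    mean_path_length: float
    mean_cluster_coefficient: float
    sigma: float
    assortativity: float
    mode: str = METABOLITE
    assortativity_defined: bool = True
    unreachable_pairs: int = 0
    replicates: int = 10
    seed: int = 0
    node_table: pd.DataFrame | None = field(default=None, repr=False)

    def scalars(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in REPORT_COLUMNS}

    def to_tsv_row(self, label: str = "network") -> str:
        header = "network\t" + "\t".join(REPORT_COLUMNS)
        values = [
            f"{v:.4G}" if isinstance(v, float) else str(v)
            for v in self.scalars().values()
        ]
        return header + "\n" + label + "\t" + "\t".join(values) + "\n"


def metrics_report(
    network: MetabolicNetwork,
    mode: str = METABOLITE,
    replicates: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Assemble every single-mode metric into one report (seed-deterministic)."""
    table = centrality_table(network, mode)
    paths = mean_path_length(network, mode)
    assort = assortativity(network, mode)
    n_met = len(network.metabolite_nodes)
    n_rxn = len(network.reaction_nodes)
    return MetricsReport(
        order_total=network.order,
        order_metabolites=n_met,
        order_reactions=n_rxn,
        size=network.size,
        density=bipartite_density(n_met, n_rxn, network.size),
        centralization_degree=centralization(table["degree_centrality"]),
        centralization_betweenness=centralization(table["betweenness_centrality"]),
        mean_path_length=paths.mean_length,
        mean_cluster_coefficient=float(table["cluster_coefficient"].mean()),
        sigma=sigma_small_world(network, mode, replicates=replicates, seed=seed),
        assortativity=assort.value,
        mode=mode,
        assortativity_defined=assort.defined,
        unreachable_pairs=paths.unreachable_pairs,
        replicates=replicates,
        seed=seed,
        node_table=table,
    )


def _round_sig(x: float, figures: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{figures}g}")


def compare_reports(a: MetricsReport, b: MetricsReport) -> pd.DataFrame:
    """Fold ratios (larger over smaller) for each scalar metric of two reports.

    Each row carries the ratio rounded to 3 significant figures and a tag
    saying which report is greater; zero denominators flag the ratio as
    infinite.
    """
    if a.mode != b.mode:
        raise ValueError("reports must refer to the same bipartite mode")
    rows = []
    for metric in REPORT_COLUMNS:
        va, vb = getattr(a, metric), getattr(b, metric)
        low, high = sorted([abs(va), abs(vb)])
        if low == 0:
            ratio, infinite = float("inf") if high else 1.0, high != 0
        else:
            ratio, infinite = high / low, False
        greater = "a" if abs(va) > abs(vb) else ("b" if abs(vb) > abs(va) else "equal")
        rows.append(
            {
                "metric": metric,
                "fold": _round_sig(ratio),
                "greater": greater,
                "infinite": infinite,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
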