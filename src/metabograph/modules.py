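"""Active-module detection: clusters of proximal metabolites with small p-values.

Each measured metabolite receives a z-score ``z = Phi^-1(1 - p)``; a candidate
subnetwork aggregates its k scored members by the Stouffer statistic
``z_A = sum(z_i) / sqrt(k)``.  A deterministic greedy search grows a cluster
from every scored metabolite seed within a bounded link depth, accepting the
neighbor that most increases ``z_A`` until no addition improves the score.
Candidates rank by score, and a Jaccard overlap threshold suppresses
near-duplicates.  Mechanical post-filters keep small clusters (few reactions,
mostly measured metabolites) that show both accumulation and depletion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .network import METABOLITE, REACTION, MetabolicNetwork

logger = logging.getLogger(__name__)

#: Finite stand-in for the -infinity quantile at p = 1.
Z_FLOOR = -10.0


def node_z_scores(comparisons: pd.DataFrame) -> dict[str, float]:
    """Standard-normal quantile z = Phi^-1(1 - p) per matched metabolite.

    p-values must lie in (0, 1]; p = 1 maps to the finite floor ``Z_FLOOR``
    with a logged flag.  Unmatched analytes contribute nothing.
    """
    scores: dict[str, float] = {}
    for _, row in comparisons.iterrows():
        metabolite = row["metabolite"]
        if metabolite is None or pd.isna(metabolite):
            continue
        p = float(row["p_value"])
        if not 0 < p <= 1:
            raise ValueError(f"p-value out of (0, 1]: {p} for {metabolite}")
        z = norm.ppf(1.0 - p)
        if not np.isfinite(z) or z < Z_FLOOR:
            logger.info("metabolite %s: z clamped to floor %.1f", metabolite, Z_FLOOR)
            z = Z_FLOOR
        scores[metabolite] = float(z)
    return scores


def score_subnetwork(nodes, z_scores: dict[str, float]) -> float:
    """Stouffer aggregate ``z_A = sum(z_i) / sqrt(k)`` over scored members."""
    scored = [z_scores[n] for n in nodes if n in z_scores]
    if not scored:
        raise ValueError("subnetwork holds no scored metabolite")
    return sum(scored) / math.sqrt(len(scored))


@dataclass
class ClusterResult:
    """A scored connected subnetwork with per-metabolite annotations."""

    nodes: set[str]
    score: float
    seed: str
    depth: int
    overlap_threshold: float
    annotations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def metabolites(self, network: MetabolicNetwork) -> list[str]:
        return sorted(
            n for n in self.nodes if network.graph.nodes[n]["kind"] == METABOLITE
        )

    def reactions(self, network: MetabolicNetwork) -> list[str]:
        return sorted(
            n for n in self.nodes if network.graph.nodes[n]["kind"] == REACTION
        )


def _scored_within(
    graph: nx.Graph, z_by_node: dict[str, float], sources, depth: int
) -> set[str]:
    """Scored metabolite nodes within ``depth`` links of any source node."""
    out: set[str] = set()
    for source in sources:
        lengths = nx.single_source_shortest_path_length(graph, source, cutoff=depth)
        out.update(n for n in lengths if n in z_by_node)
    return out


def _grow_cluster(
    network: MetabolicNetwork,
    z_by_node: dict[str, float],
    seed: str,
    depth: int,
) -> tuple[set[str], float]:
    """Greedy hill-climb from one seed; returns (node set, z_A).

    Each step considers scored metabolites within ``depth`` links of the
    current cluster, accepts the one that most increases ``z_A``, and adds
    the lexicographically smallest shortest connecting path (whose reaction
    nodes become unscored connectors) so the cluster stays connected.
    """
    graph = network.graph
    undirected = graph.to_undirected(as_view=True)
    members = {seed}
    connectors: set[str] = set()
    score = score_subnetwork(members, z_by_node)
    candidates = _scored_within(undirected, z_by_node, members, depth) - members
    while True:
        best: tuple[float, str] | None = None
        for candidate in sorted(candidates):
            trial = score_subnetwork(members | {candidate}, z_by_node)
            if trial > score and (best is None or trial > best[0]):
                best = (trial, candidate)
        if best is None:
            break
        score, chosen = best
        # smallest shortest path from the cluster to the accepted node
        path = min(
            nx.all_shortest_paths(
                undirected,
                min(members | connectors, key=lambda m: _distance(undirected, m, chosen)),
                chosen,
            )
        )
        for node in path:
            if node in z_by_node:
                members.add(node)
            else:
                connectors.add(node)
        score = score_subnetwork(members, z_by_node)
        candidates |= _scored_within(undirected, z_by_node, {chosen}, depth)
        candidates -= members
    return members | connectors, score


def _distance(graph: nx.Graph, source: str, target: str) -> int:
    try:
        return nx.shortest_path_length(graph, source, target)
    except nx.NetworkXNoPath:
        return 10**9


def _jaccard(a: set[str], b: set[str]) -> float:
    return len(a & b) / len(a | b)


def search_modules(
    network: MetabolicNetwork,
    z_scores: dict[str, float],
    n_modules: int = 25,
    depth: int = 2,
    overlap_thresholds: tuple[float, ...] = (0.25, 0.50, 0.75),
    seed: int = 0,
) -> list[ClusterResult]:
    """Greedy cluster search from every scored metabolite node.

    Emits up to ``n_modules`` clusters per overlap threshold, ranked by
    ``z_A`` and suppressing any candidate whose Jaccard node overlap with an
    already-emitted cluster exceeds the threshold.  Deterministic: ties break
    by seed identifier; ``seed`` is recorded for provenance.
    """
    graph = network.graph
    z_by_node = {
        node: z_scores[graph.nodes[node].get("metabolite", node)]
        for node in graph
        if graph.nodes[node]["kind"] == METABOLITE
        and graph.nodes[node].get("metabolite", node) in z_scores
    }
    if not z_by_node:
        logger.warning("no scored metabolite nodes; empty module search")
        return []
    candidates: list[ClusterResult] = []
    for seed_node in sorted(z_by_node):
        nodes, score = _grow_cluster(network, z_by_node, seed_node, depth)
        annotations = {
            n: (
                graph.nodes[n].get("log2fc", float("nan")),
                graph.nodes[n].get("p_value", float("nan")),
            )
            for n in nodes
            if n in z_by_node
        }
        candidates.append(
            ClusterResult(
                nodes=nodes,
                score=score,
                seed=seed_node,
                depth=depth,
                overlap_threshold=float("nan"),
                annotations=annotations,
            )
        )
    candidates.sort(key=lambda c: (-c.score, c.seed))
    results: list[ClusterResult] = []
    for threshold in overlap_thresholds:
        emitted: list[ClusterResult] = []
        for candidate in candidates:
            if len(emitted) >= n_modules:
                break
            if any(_jaccard(candidate.nodes, e.nodes) > threshold for e in emitted):
                continue
            emitted.append(
                ClusterResult(
                    nodes=set(candidate.nodes),
                    score=candidate.score,
                    seed=candidate.seed,
                    depth=depth,
                    overlap_threshold=threshold,
                    annotations=dict(candidate.annotations),
                )
            )
        results.extend(emitted)
    return results


def filter_clusters(
    clusters: list[ClusterResult], network: MetabolicNetwork
) -> list[ClusterResult]:
    """Mechanical prioritization of small, well-measured, bidirectional clusters.

    Keeps clusters with at most 3 reaction nodes, in which every reaction's
    in-cluster participant metabolites are mostly measured, and whose
    measured metabolites show both accumulation (log2FC > 0) and depletion
    (log2FC < 0).  Idempotent; output is a subset of input.
    """
    graph = network.graph
    undirected = graph.to_undirected(as_view=True)
    kept = []
    for cluster in clusters:
        reactions = cluster.reactions(network)
        if len(reactions) > 3:
            continue
        majority_measured = True
        for reaction in reactions:
            in_cluster = [
                m
                for m in undirected[reaction]
                if m in cluster.nodes and graph.nodes[m]["kind"] == METABOLITE
            ]
            measured = [m for m in in_cluster if m in cluster.annotations]
            if in_cluster and len(measured) * 2 <= len(in_cluster):
                majority_measured = False
                break
        if not majority_measured:
            continue
        folds = [fc for fc, _ in cluster.annotations.values() if np.isfinite(fc)]
        if not (any(f > 0 for f in folds) and any(f < 0 for f in folds)):
            continue
        kept.append(cluster)
    return kept


def export_clusters(
    clusters: list[ClusterResult], network: MetabolicNetwork, path_prefix
) -> None:
    """Write metabolite and reaction membership tables as TSVs.

    ``<prefix>_metabolites.tsv``: cluster, identifier, name, log2fc, p_value.
    ``<prefix>_reactions.tsv``: cluster, identifier, name, genes, processes.
    """
    graph = network.graph
    with open(f"{path_prefix}_metabolites.tsv", "w", encoding="utf-8") as handle:
        handle.write("cluster\tidentifier\tname\tlog2fc\tp_value\tscore\n")
        for index, cluster in enumerate(clusters):
            for node in cluster.metabolites(network):
                fc, p = cluster.annotations.get(node, (float("nan"), float("nan")))
                handle.write(
                    f"{index}\t{node}\t{graph.nodes[node].get('name', '')}\t"
                    f"{fc:.6g}\t{p:.6g}\t{cluster.score:.6g}\n"
                )
    with open(f"{path_prefix}_reactions.tsv", "w", encoding="utf-8") as handle:
        handle.write("cluster\tidentifier\tname\tgenes\tprocesses\n")
        for index, cluster in enumerate(clusters):
            for node in cluster.reactions(network):
                data = graph.nodes[node]
                genes = ";".join(data.get("genes", []))
                processes = ";".join(data.get("processes", []))
                handle.write(
                    f"{index}\t{node}\t{data.get('name', '')}\t{genes}\t{processes}\n"
                )


def read_cluster_membership(path_prefix) -> dict[int, set[str]]:
    """Reload cluster node membership from exported TSVs (round-trip check)."""
    membership: dict[int, set[str]] = {}
    for suffix in ("_metabolites.tsv", "_reactions.tsv"):
        with open(f"{path_prefix}{suffix}", encoding="utf-8") as handle:
            next(handle)
            for line in handle:
                cells = line.rstrip("\n").split("\t")
                membership.setdefault(int(cells[0]), set()).add(cells[1])
    return membership
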