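"""Directional bipartite metabolite-reaction network construction and queries.

A metabolic network places metabolites and reactions on opposite sides of a
bipartite partition.  Reactant metabolites link into their reactions and
reactions link out to their products; a reversible reaction defines links in
both directions for every participant.  Three constraints shape the network:

1. *Compartmentalization* — either one node per (metabolite, compartment)
   pair with transport reactions retained, or a single consensus node per
   chemical entity with pure transport reactions excluded and chemically
   redundant reactions merged.
2. *Compartment / process filters* — restrict to reactions whose
   compartments all pass the compartment filter and that belong to at least
   one process in the process filter.
3. *Metabolite exclusion* — drop nodes for named hub metabolites and for
   metabolites whose degree exceeds a threshold; the reactions' own
   participant payloads still record the excluded metabolites.

Node identifiers: compartmental metabolite nodes are ``<metabolite>@<compartment>``;
consensus metabolite nodes use the bare metabolite identifier; reaction
nodes use the reaction identifier (for merged consensus reactions, the
lexicographically smallest member identifier).  All tie-breaks are
lexicographic so outputs are deterministic.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .model import MetabolicModel, Reaction

logger = logging.getLogger(__name__)

METABOLITE = "metabolite"
REACTION = "reaction"
# Link roles: a metabolite->reaction link is a "reactant" role, a
# reaction->metabolite link a "product" role, regardless of whether the link
# came from reversibility.
ROLE_REACTANT = "reactant"
ROLE_PRODUCT = "product"


class EmptyNetworkError(ValueError):
    """Raised when filters exclude every reaction."""


@dataclass
class NetworkSpec:
    """Definition parameters for a bipartite metabolic network."""

    compartmentalize: bool = True
    compartment_filter: set[str] | None = None
    process_filter: set[str] | None = None
    excluded_metabolites: set[str] = field(default_factory=set)
    degree_threshold: int | None = None
    keep_largest_component: bool = True
    exclude_transport_conversions: bool = False  # also drop "both" reactions

    def __post_init__(self) -> None:
        if self.degree_threshold is not None and self.degree_threshold < 1:
            raise ValueError("degree_threshold must be >= 1")
        self.excluded_metabolites = set(self.excluded_metabolites)

    def describe(self) -> str:
        return (
            f"compartmentalize={self.compartmentalize} "
            f"excluded={len(self.excluded_metabolites)} "
            f"degree_threshold={self.degree_threshold}"
        )


@dataclass
class MetabolicNetwork:
    """A directed bipartite graph plus the spec that produced it."""

    graph: nx.DiGraph
    spec: NetworkSpec
    provenance: str = ""

    @property
    def metabolite_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == METABOLITE
        )

    @property
    def reaction_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == REACTION
        )

    @property
    def order(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def size(self) -> int:
        return self.graph.number_of_edges()

    def assert_bipartite(self) -> None:
        for source, target in self.graph.edges():
            kinds = {self.graph.nodes[source]["kind"], self.graph.nodes[target]["kind"]}
            if kinds != {METABOLITE, REACTION}:
                raise AssertionError(
                    f"link {source}->{target} violates bipartiteness"
                )

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)


@dataclass
class Subnetwork(MetabolicNetwork):
    """Induced subgraph of a parent network with query provenance."""


def _included_reactions(model: MetabolicModel, spec: NetworkSpec) -> list[Reaction]:
    reactions = []
    for reaction in model.reactions.values():
        if spec.compartment_filter is not None and not (
            reaction.compartments() <= spec.compartment_filter
        ):
            continue
        if spec.process_filter is not None and not (
            set(reaction.processes) & spec.process_filter
        ):
            continue
        reactions.append(reaction)
    return reactions


def _add_reaction_links(
    graph: nx.DiGraph, reaction_node: str, reaction: Reaction, node_of
) -> None:
    """Add links for one reaction; duplicate links collapse to one."""
    for part in reaction.participants:
        met_node = node_of(part)
        if part.role == "reactant":
            graph.add_edge(met_node, reaction_node, role=ROLE_REACTANT)
            if reaction.reversible:
                graph.add_edge(reaction_node, met_node, role=ROLE_PRODUCT)
        else:
            graph.add_edge(reaction_node, met_node, role=ROLE_PRODUCT)
            if reaction.reversible:
                graph.add_edge(met_node, reaction_node, role=ROLE_REACTANT)


def build_compartmental(model: MetabolicModel, spec: NetworkSpec) -> MetabolicNetwork:
    """One metabolite node per (metabolite, compartment) pair; transports kept."""
    if not spec.compartmentalize:
        raise ValueError("spec.compartmentalize must be true for a compartmental build")
    reactions = _included_reactions(model, spec)
    if not reactions:
        raise EmptyNetworkError(
            f"no reaction passes the filters ({spec.describe()})"
        )
    graph = nx.DiGraph()
    for reaction in sorted(reactions, key=lambda r: r.identifier):
        graph.add_node(
            reaction.identifier,
            kind=REACTION,
            name=reaction.name,
            reversible=reaction.reversible,
            behavior=reaction.behavior,
            sources=[reaction.identifier],
        )
        for part in reaction.participants:
            node = f"{part.metabolite}@{part.compartment}"
            if node not in graph:
                met = model.metabolites[part.metabolite]
                graph.add_node(
                    node,
                    kind=METABOLITE,
                    name=met.name,
                    metabolite=part.metabolite,
                    compartment=part.compartment,
                    sources=[node],
                )
        _add_reaction_links(
            graph,
            reaction.identifier,
            reaction,
            lambda p: f"{p.metabolite}@{p.compartment}",
        )
    network = MetabolicNetwork(graph, spec, provenance="compartmental build")
    network.assert_bipartite()
    return network


def _consensus_key(reaction: Reaction) -> tuple:
    """Chemistry key: multiset of (metabolite, role, stoichiometry), reversibility."""
    parts = tuple(
        sorted((p.metabolite, p.role, p.stoichiometry) for p in reaction.participants)
    )
    return (parts, reaction.reversible)


def build_noncompartmental(
    model: MetabolicModel, spec: NetworkSpec
) -> MetabolicNetwork:
    """Consensus metabolite nodes; pure transports dropped; redundant reactions merged."""
    if spec.compartmentalize:
        raise ValueError(
            "spec.compartmentalize must be false for a non-compartmental build"
        )
    excluded_behaviors = {"transport"}
    if spec.exclude_transport_conversions:
        excluded_behaviors.add("both")
    reactions = [
        r
        for r in _included_reactions(model, spec)
        if r.behavior not in excluded_behaviors
    ]
    if not reactions:
        raise EmptyNetworkError(
            f"no reaction passes the filters ({spec.describe()})"
        )

    groups: dict[tuple, list[Reaction]] = {}
    for reaction in reactions:
        groups.setdefault(_consensus_key(reaction), []).append(reaction)

    graph = nx.DiGraph()
    for _, members in sorted(
        groups.items(), key=lambda kv: min(r.identifier for r in kv[1])
    ):
        members.sort(key=lambda r: r.identifier)
        leader = members[0]
        node = leader.identifier
        processes = sorted({p for r in members for p in r.processes})
        genes = sorted({g for r in members for g in r.genes})
        references: dict[str, list[str]] = {}
        for member in members:
            for namespace, values in member.references.items():
                bucket = references.setdefault(namespace, [])
                for value in values:
                    if value not in bucket:
                        bucket.append(value)
        graph.add_node(
            node,
            kind=REACTION,
            name=leader.name,
            reversible=leader.reversible,
            behavior=leader.behavior,
            sources=[r.identifier for r in members],
            processes=processes,
            genes=genes,
            references=references,
        )
        for part in leader.participants:
            if part.metabolite not in graph:
                met = model.metabolites[part.metabolite]
                compartmental_sources = sorted(
                    {
                        f"{p.metabolite}@{p.compartment}"
                        for r in members
                        for p in r.participants
                        if p.metabolite == part.metabolite
                    }
                )
                graph.add_node(
                    part.metabolite,
                    kind=METABOLITE,
                    name=met.name,
                    metabolite=part.metabolite,
                    references=met.references,
                    sources=compartmental_sources,
                )
        _add_reaction_links(graph, node, leader, lambda p: p.metabolite)
    network = MetabolicNetwork(graph, spec, provenance="non-compartmental build")
    network.assert_bipartite()
    return network


def apply_exclusions(network: MetabolicNetwork, spec: NetworkSpec) -> MetabolicNetwork:
    """Drop excluded and over-threshold metabolite nodes.

    Degrees (in + out links) are measured on the network *before* any
    exclusion so that list-based and degree-based exclusion commute.
    Reaction payloads keep their full participant information.
    """
    graph = network.graph.copy()
    degree = dict(graph.degree())
    to_drop: set[str] = set()
    known_metabolites = {
        graph.nodes[n].get("metabolite", n)
        for n in graph
        if graph.nodes[n]["kind"] == METABOLITE
    }
    for excluded in spec.excluded_metabolites:
        if excluded not in known_metabolites:
            logger.warning("exclusion list names unknown metabolite %r", excluded)
    for node, data in graph.nodes(data=True):
        if data["kind"] != METABOLITE:
            continue
        if data.get("metabolite", node) in spec.excluded_metabolites:
            to_drop.add(node)
        elif spec.degree_threshold is not None and degree[node] > spec.degree_threshold:
            to_drop.add(node)
    graph.remove_nodes_from(to_drop)
    out = MetabolicNetwork(
        graph, spec, provenance=network.provenance + " + exclusions"
    )
    out.assert_bipartite()
    return out


def largest_component(network: MetabolicNetwork) -> MetabolicNetwork:
    """Induced subgraph on the largest weakly connected component.

    Ties break toward the component containing the lexicographically
    smallest node identifier.  An empty network maps to an empty network.
    """
    if network.order == 0:
        return MetabolicNetwork(
            nx.DiGraph(), network.spec, provenance=network.provenance + " + component"
        )
    components = sorted(
        nx.weakly_connected_components(network.graph),
        key=lambda c: (-len(c), min(c)),
    )
    graph = network.graph.subgraph(components[0]).copy()
    return MetabolicNetwork(
        graph, network.spec, provenance=network.provenance + " + component"
    )


def build_network(model: MetabolicModel, spec: NetworkSpec) -> MetabolicNetwork:
    """Full definition pipeline: build, exclude, largest component."""
    if spec.compartmentalize:
        network = build_compartmental(model, spec)
    else:
        network = build_noncompartmental(model, spec)
    network = apply_exclusions(network, spec)
    if spec.keep_largest_component:
        network = largest_component(network)
    return network


# ---------------------------------------------------------------------------
# Queries


def query_proximity(
    network: MetabolicNetwork, focus: str, depth: int, direction: str = "both"
) -> Subnetwork:
    """Breadth-first neighborhood of ``focus`` within ``depth`` links."""
    graph = network.graph
    if focus not in graph:
        raise KeyError(f"focus node {focus!r} not in network")
    if direction not in ("out", "in", "both"):
        raise ValueError(f"invalid direction {direction!r}")
    visited = {focus: 0}
    queue = deque([focus])
    while queue:
        node = queue.popleft()
        if visited[node] == depth:
            continue
        neighbors: set[str] = set()
        if direction in ("out", "both"):
            neighbors.update(graph.successors(node))
        if direction in ("in", "both"):
            neighbors.update(graph.predecessors(node))
        for neighbor in sorted(neighbors):
            if neighbor not in visited:
                visited[neighbor] = visited[node] + 1
                queue.append(neighbor)
    sub = graph.subgraph(visited).copy()
    return Subnetwork(
        sub,
        network.spec,
        provenance=f"proximity(focus={focus}, depth={depth}, direction={direction})",
    )


def query_connection(network: MetabolicNetwork, targets: set[str]) -> Subnetwork:
    """Union of directed simple shortest paths between every ordered pair."""
    targets = sorted(targets)
    if len(targets) < 2:
        raise ValueError("connection query requires >= 2 targets")
    graph = network.graph
    missing = [t for t in targets if t not in graph]
    if missing:
        raise KeyError(f"targets not in network: {missing}")
    nodes: set[str] = set(targets)
    unreachable: list[tuple[str, str]] = []
    for source in targets:
        for target in targets:
            if source == target:
                continue
            try:
                for path in nx.all_shortest_paths(graph, source, target):
                    nodes.update(path)
            except nx.NetworkXNoPath:
                unreachable.append((source, target))
    provenance = f"connection(targets={targets})"
    if unreachable:
        provenance += f" unreachable={unreachable}"
    sub = graph.subgraph(nodes).copy()
    return Subnetwork(sub, network.spec, provenance=provenance)


# ---------------------------------------------------------------------------
# Export


def export_network(network: MetabolicNetwork, path, format: str = "graphml") -> None:
    """Write GraphML, node-link JSON, or Cytoscape-ready node/edge TSVs.

    For ``cytoscape_tables``, ``path`` is a prefix: ``<path>_nodes.tsv`` and
    ``<path>_edges.tsv`` are written.
    """
    if format == "graphml":
        graph = network.graph.copy()
        for _, data in graph.nodes(data=True):
            for key, value in list(data.items()):
                if isinstance(value, (list, dict)):
                    data[key] = json.dumps(value)
        nx.write_graphml(graph, path)
    elif format == "node_link_text":
        data = nx.node_link_data(network.graph, edges="links")
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(data, handle, ensure_ascii=False, indent=1, sort_keys=True)
            handle.write("\n")
    elif format == "cytoscape_tables":
        degree = dict(network.graph.degree())
        with open(f"{path}_nodes.tsv", "w", encoding="utf-8") as handle:
            handle.write("identifier\ttype\tname\tdegree\tannotations\n")
            for node in sorted(network.graph.nodes):
                data = network.graph.nodes[node]
                annotations = {
                    k: v
                    for k, v in data.items()
                    if k not in ("kind", "name") and v is not None
                }
                handle.write(
                    f"{node}\t{data['kind']}\t{data.get('name', '')}\t"
                    f"{degree[node]}\t{json.dumps(annotations, sort_keys=True)}\n"
                )
        with open(f"{path}_edges.tsv", "w", encoding="utf-8") as handle:
            handle.write("source\ttarget\trole\n")
            for source, target, data in sorted(network.graph.edges(data=True)):
                handle.write(f"{source}\t{target}\t{data.get('role', '')}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graphml(path, spec: NetworkSpec | None = None) -> MetabolicNetwork:
    """Read a GraphML export back; inverse of ``export_network`` on topology."""
    graph = nx.read_graphml(path)
    out = nx.DiGraph()
    for node, data in graph.nodes(data=True):
        decoded = dict(data)
        for key, value in list(decoded.items()):
            if isinstance(value, str) and value[:1] in "[{":
                try:
                    decoded[key] = json.loads(value)
                except json.JSONDecodeError:
                    pass
        out.add_node(node, **decoded)
    for source, target, data in graph.edges(data=True):
        out.add_edge(source, target, **data)
    network = MetabolicNetwork(out, spec or NetworkSpec(), provenance=f"graphml:{path}")
    network.assert_bipartite()
    return network
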