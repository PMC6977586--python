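"""Brute-force graph oracles, independent of the library implementations.

Everything here works on plain adjacency dictionaries extracted from the
graph's edge list, enumerating shortest paths explicitly.  Intended for
fixtures of at most a few dozen nodes.
"""

from collections import deque


def adjacency(graph) -> dict:
    adj = {node: [] for node in graph.nodes}
    for source, target in graph.edges:
        adj[source].append(target)
    return adj


def undirected_adjacency(graph) -> dict:
    adj = {node: set() for node in graph.nodes}
    for source, target in graph.edges:
        adj[source].add(target)
        adj[target].add(source)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    distances = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for neighbor in adj[node]:
            if neighbor not in distances:
                distances[neighbor] = distances[node] + 1
                queue.append(neighbor)
    return distances


def enumerate_shortest_paths(adj: dict, source, target) -> list[list]:
    """All shortest directed paths source->target by DFS over tight edges."""
    distances = bfs_distances(adj, source)
    if target not in distances:
        return []
    paths = []

    def extend(path):
        node = path[-1]
        if node == target:
            paths.append(list(path))
            return
        for neighbor in adj[node]:
            if distances.get(neighbor) == distances[node] + 1 and distances[neighbor] <= distances[target]:
                extend(path + [neighbor])

    extend([source])
    return paths


def oracle_betweenness(graph) -> dict:
    """Raw directed betweenness by explicit path enumeration."""
    adj = adjacency(graph)
    scores = {node: 0.0 for node in adj}
    for source in adj:
        for target in adj:
            if source == target:
                continue
            paths = enumerate_shortest_paths(adj, source, target)
            if not paths:
                continue
            for node in adj:
                if node in (source, target):
                    continue
                through = sum(node in path for path in paths)
                scores[node] += through / len(paths)
    return scores


def oracle_mean_path(graph, nodes) -> tuple[float, int]:
    """Mean directed shortest-path length and unreachable count, same-set pairs."""
    adj = adjacency(graph)
    node_set = set(nodes)
    total, reachable, unreachable = 0, 0, 0
    for source in nodes:
        distances = bfs_distances(adj, source)
        for target in nodes:
            if target == source:
                continue
            if target in distances:
                total += distances[target]
                reachable += 1
            else:
                unreachable += 1
    return total / reachable, unreachable


def oracle_clustering(graph, nodes) -> dict:
    """Mean Jaccard overlap with second-order neighbors (undirected view)."""
    adj = undirected_adjacency(graph)
    out = {}
    for node in nodes:
        first = adj[node]
        second = set()
        for neighbor in first:
            second |= adj[neighbor]
        second.discard(node)
        if not second:
            out[node] = 0.0
            continue
        values = [
            len(first & adj[other]) / len(first | adj[other]) for other in second
        ]
        out[node] = sum(values) / len(values)
    return out


def oracle_projection(graph, nodes) -> set:
    """Single-mode projection links by pairwise traversal through reactions."""
    node_set = set(nodes)
    links = set()
    for u in nodes:
        for via in graph.successors(u):
            for w in graph.successors(via):
                if w in node_set and w != u:
                    links.add((u, w))
    return links
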