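"""Single-mode metric computations against hand values and brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import metabograph as mg
from _oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_mean_path,
    oracle_projection,
)
from metabograph.metrics import (
    MetricsReport,
    PathSummary,
    project_single_mode,
    raw_betweenness,
)


def _fixture_networks(toy4_network, toyhub_model, toycomp_model, star_network, tree_network):
    return {
        "toy4": toy4_network,
        "toyhub": mg.build_network(toyhub_model, mg.NetworkSpec(compartmentalize=True)),
        "toycomp": mg.build_network(toycomp_model, mg.NetworkSpec(compartmentalize=True)),
        "star": star_network,
        "tree": tree_network,
    }


# ---------------------------------------------------------------------------
# density


def test_density_toy4():
    assert mg.bipartite_density(4, 4, 8) == 0.25


def test_density_zero_size():
    assert mg.bipartite_density(4, 4, 0) == 0.0


def test_density_empty_set_raises():
    with pytest.raises(ValueError):
        mg.bipartite_density(0, 4, 0)


# ---------------------------------------------------------------------------
# centralities


def test_degree_centrality_toy4(toy4_network):
    values = mg.degree_centrality(toy4_network, "metabolite")
    assert values["A@c"] == pytest.approx(2 / 8)
    assert (values == 0.25).all()


def test_degree_centrality_saturation():
    graph = nx.DiGraph()
    graph.add_node("m", kind="metabolite")
    for i in range(3):
        graph.add_node(f"r{i}", kind="reaction")
        graph.add_edge("m", f"r{i}", role="reactant")
        graph.add_edge(f"r{i}", "m", role="product")
    net = mg.MetabolicNetwork(graph, mg.NetworkSpec())
    assert mg.degree_centrality(net, "metabolite")["m"] == 1.0


def test_degree_centrality_isolated_node_zero(toy4_network):
    graph = toy4_network.graph.copy()
    graph.add_node("iso", kind="metabolite")
    net = mg.MetabolicNetwork(graph, toy4_network.spec)
    assert mg.degree_centrality(net, "metabolite")["iso"] == 0.0


def test_betweenness_symmetric_on_cycle(toy4_network):
    values = mg.betweenness_centrality(toy4_network, "metabolite")
    assert values.nunique() == 1  # all metabolites equivalent by symmetry


def test_betweenness_star_center_dominates(star_network):
    values = mg.betweenness_centrality(star_network, "metabolite")
    assert values.idxmax() == "hub"
    assert values["hub"] > values.drop("hub").max()


def test_betweenness_two_node_network_zero():
    graph = nx.DiGraph()
    graph.add_node("m", kind="metabolite")
    graph.add_node("r", kind="reaction")
    graph.add_edge("m", "r", role="reactant")
    net = mg.MetabolicNetwork(graph, mg.NetworkSpec())
    assert (mg.betweenness_centrality(net, "metabolite") == 0).all()


def test_raw_betweenness_matches_enumeration_oracle(
    toy4_network, toyhub_model, toycomp_model, star_network, tree_network
):
    for name, net in _fixture_networks(
        toy4_network, toyhub_model, toycomp_model, star_network, tree_network
    ).items():
        expected = oracle_betweenness(net.graph)
        actual = raw_betweenness(net)
        for node, value in expected.items():
            assert actual[node] == pytest.approx(value), (name, node)


# ---------------------------------------------------------------------------
# centralization


@pytest.mark.parametrize(
    "values, expected",
    [([0.4, 0.4, 0.4], 0.0), ([1.0, 0.0, 0.0], 1.0), ([0.5, 0.25, 0.25], 0.25)],
)
def test_centralization_hand_values(values, expected):
    assert mg.centralization(values) == pytest.approx(expected)


def test_centralization_requires_two_nodes():
    with pytest.raises(ValueError):
        mg.centralization([0.5])


# ---------------------------------------------------------------------------
# clustering


def test_clustering_toy4_hand_value(toy4_network):
    values = mg.bipartite_clustering(toy4_network, "metabolite")
    assert values["A@c"] == pytest.approx(1 / 3)


def test_clustering_identical_reaction_neighborhoods():
    # two reactions sharing exactly the same metabolite pair
    graph = nx.DiGraph()
    for met in ("a", "b"):
        graph.add_node(met, kind="metabolite")
    for rxn in ("r1", "r2"):
        graph.add_node(rxn, kind="reaction")
        graph.add_edge("a", rxn, role="reactant")
        graph.add_edge(rxn, "b", role="product")
    net = mg.MetabolicNetwork(graph, mg.NetworkSpec())
    values = mg.bipartite_clustering(net, "reaction")
    assert values["r1"] == 1.0 and values["r2"] == 1.0


def test_clustering_tree_is_zero_for_disjoint_neighborhoods(tree_network):
    values = mg.bipartite_clustering(tree_network, "reaction")
    # the two reactions share only the root metabolite
    assert (values < 1).all()
    leaves = mg.bipartite_clustering(tree_network, "metabolite")
    assert leaves["m00"] == pytest.approx(
        oracle_clustering(tree_network.graph, ["m00"])["m00"]
    )


def test_clustering_matches_oracle_on_fixtures(
    toy4_network, toyhub_model, toycomp_model, star_network, tree_network
):
    for name, net in _fixture_networks(
        toy4_network, toyhub_model, toycomp_model, star_network, tree_network
    ).items():
        for mode in ("metabolite", "reaction"):
            nodes = getattr(net, f"{mode}_nodes")
            expected = oracle_clustering(net.graph, nodes)
            actual = mg.bipartite_clustering(net, mode)
            for node in nodes:
                assert actual[node] == pytest.approx(expected[node]), (name, node)


# ---------------------------------------------------------------------------
# path lengths


def test_mean_path_toy4(toy4_network):
    summary = mg.mean_path_length(toy4_network, "metabolite")
    assert summary.mean_length == pytest.approx(4.0)  # (2+4+6)/3
    assert summary.unreachable_pairs == 0


def test_mean_path_single_reaction():
    graph = nx.DiGraph()
    graph.add_node("A", kind="metabolite")
    graph.add_node("B", kind="metabolite")
    graph.add_node("r", kind="reaction")
    graph.add_edge("A", "r", role="reactant")
    graph.add_edge("r", "B", role="product")
    net = mg.MetabolicNetwork(graph, mg.NetworkSpec())
    summary = mg.mean_path_length(net, "metabolite")
    assert summary.mean_length == 2.0
    assert summary.unreachable_pairs == 1  # B cannot reach A


def test_mean_path_matches_oracle_on_fixtures(
    toy4_network, toyhub_model, toycomp_model, star_network, tree_network
):
    for name, net in _fixture_networks(
        toy4_network, toyhub_model, toycomp_model, star_network, tree_network
    ).items():
        expected_mean, expected_unreachable = oracle_mean_path(
            net.graph, net.metabolite_nodes
        )
        summary = mg.mean_path_length(net, "metabolite")
        assert summary.mean_length == pytest.approx(expected_mean), name
        assert summary.unreachable_pairs == expected_unreachable, name


# ---------------------------------------------------------------------------
# random ensembles and sigma


def test_random_bipartite_deterministic():
    a = mg.random_bipartite(5, 6, 20, seed=9)
    b = mg.random_bipartite(5, 6, 20, seed=9)
    assert set(a.graph.edges) == set(b.graph.edges)


def test_random_bipartite_complete():
    net = mg.random_bipartite(3, 3, 18, seed=0)
    assert net.size == 18
    net.assert_bipartite()


def test_random_bipartite_infeasible_size():
    with pytest.raises(ValueError):
        mg.random_bipartite(2, 2, 9, seed=0)


def test_random_bipartite_density_exact_by_construction():
    densities = [
        mg.bipartite_density(6, 6, mg.random_bipartite(6, 6, 18, seed=s).size)
        for s in range(20)
    ]
    assert all(d == 0.25 for d in densities)


def test_sigma_definitional_identity(toy4_network, monkeypatch):
    # a network measured against itself as its own ensemble
    monkeypatch.setattr(
        mg.metrics, "random_bipartite", lambda *a, **k: toy4_network
    )
    assert mg.sigma_small_world(toy4_network, "metabolite", replicates=3, seed=0) == 1.0


def test_sigma_toy4_seeded_regression(toy4_network):
    value = mg.sigma_small_world(toy4_network, "metabolite", replicates=10, seed=42)
    assert value == pytest.approx(0.3662790697674419, rel=1e-9)


# ---------------------------------------------------------------------------
# assortativity


def test_assortativity_constant_degrees_flagged(toy4_network):
    result = mg.assortativity(toy4_network, "metabolite")
    assert result.value == 0.0 and not result.defined


def test_assortativity_star_negative(star_network):
    result = mg.assortativity(star_network, "metabolite")
    assert result.defined and result.value < 0


def test_projection_matches_traversal_oracle(
    toy4_network, toyhub_model, toycomp_model, star_network, tree_network
):
    for name, net in _fixture_networks(
        toy4_network, toyhub_model, toycomp_model, star_network, tree_network
    ).items():
        projection = project_single_mode(net, "metabolite")
        assert set(projection.edges) == oracle_projection(
            net.graph, net.metabolite_nodes
        ), name


def test_toy4_projection_is_directed_cycle(toy4_network):
    projection = project_single_mode(toy4_network, "metabolite")
    assert set(projection.edges) == {
        ("A@c", "B@c"), ("B@c", "C@c"), ("C@c", "D@c"), ("D@c", "A@c")
    }


# ---------------------------------------------------------------------------
# ranks


def test_rank_metabolites_hand_example():
    table = pd.DataFrame(
        {
            "degree_centrality": {"A": 0.5, "B": 0.3, "C": 0.1},
            "betweenness_centrality": {"A": 0.5, "B": 0.6, "C": 0.1},
        }
    )
    ranks = mg.rank_metabolites(table)
    assert ranks.loc["A", "total_rank"] == 1.5
    assert ranks.loc["B", "total_rank"] == 1.5
    assert ranks.loc["C", "total_rank"] == 3.0
    assert list(ranks.index) == ["A", "B", "C"]


def test_rank_single_node():
    table = pd.DataFrame(
        {"degree_centrality": {"A": 0.2}, "betweenness_centrality": {"A": 0.0}}
    )
    ranks = mg.rank_metabolites(table)
    assert ranks.loc["A"].tolist() == [1.0, 1.0, 1.0]


def test_rank_all_equal_gives_average_rank():
    table = pd.DataFrame(
        {
            "degree_centrality": {"A": 0.2, "B": 0.2, "C": 0.2},
            "betweenness_centrality": {"A": 0.1, "B": 0.1, "C": 0.1},
        }
    )
    ranks = mg.rank_metabolites(table)
    assert (ranks["total_rank"] == 2.0).all()


def test_degree_ranks_sum_to_triangular_number(toyhub_model):
    net = mg.build_network(toyhub_model, mg.NetworkSpec(compartmentalize=True))
    ranks = mg.rank_metabolites(mg.centrality_table(net, "metabolite"))
    n = len(ranks)
    assert ranks["degree_rank"].sum() == n * (n + 1) / 2


# ---------------------------------------------------------------------------
# report assembly and comparison


def test_metrics_report_toy4(toy4_network):
    report = mg.metrics_report(toy4_network, replicates=5, seed=1)
    assert (report.order_metabolites, report.order_reactions) == (4, 4)
    assert report.size == 8
    assert report.density == 0.25
    assert report.mean_path_length == pytest.approx(4.0)
    assert report.mean_cluster_coefficient == pytest.approx(1 / 3)
    assert report.order_total == report.order_metabolites + report.order_reactions


def test_report_tsv_row_column_order(toy4_network):
    report = mg.metrics_report(toy4_network, replicates=3, seed=1)
    header = report.to_tsv_row().splitlines()[0].split("\t")
    assert header[1:5] == ["order_total", "order_metabolites", "order_reactions", "size"]
    assert header[-1] == "assortativity"


def test_compare_reports_identical_all_ones(toy4_network):
    report = mg.metrics_report(toy4_network, replicates=3, seed=1)
    table = mg.compare_reports(report, report)
    assert (table["fold"] == 1.0).all()
    assert (table["greater"] == "equal").all()


def test_compare_reports_zero_denominator_flagged(toy4_network):
    a = mg.metrics_report(toy4_network, replicates=3, seed=1)
    b = MetricsReport(**{**{k: getattr(a, k) for k in mg.metrics.REPORT_COLUMNS},
                         "mode": a.mode})
    b.assortativity = 0.0
    a.assortativity = 0.1
    table = mg.compare_reports(a, b)
    assert table.loc["assortativity", "infinite"]


def test_removing_top_degree_metabolite_shrinks_network(toyhub_model):
    full = mg.build_network(toyhub_model, mg.NetworkSpec(compartmentalize=True))
    degrees = dict(full.graph.degree())
    top = max(full.metabolite_nodes, key=lambda n: degrees[n])
    spec = mg.NetworkSpec(
        compartmentalize=True,
        excluded_metabolites={full.graph.nodes[top]["metabolite"]},
    )
    reduced = mg.apply_exclusions(full, spec)
    assert reduced.size < full.size
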