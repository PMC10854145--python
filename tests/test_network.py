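import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from iwhmb import io_formats, network
from iwhmb.io_formats import InteractionNetwork


def net_from_edges(*edges):
    return InteractionNetwork(nx.Graph(edges), provenance=("test",))


class TestBuildGlobal:
    def test_union_of_sources(self):
        merged = network.build_global_network(
            [net_from_edges(("A", "B")), net_from_edges(("B", "C"))]
        )
        assert set(map(frozenset, merged.graph.edges)) == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }

    def test_idempotent_on_identical_sources(self):
        one = net_from_edges(("A", "B"))
        merged = network.build_global_network([one, one, one])
        assert merged.graph.number_of_edges() == 1

    def test_counts_disjoint_sources(self):
        sources = [
            net_from_edges(("A", "B"), ("C", "D")),
            net_from_edges(("E", "F"), ("G", "H")),
            net_from_edges(("I", "J"), ("K", "L")),
        ]
        assert network.build_global_network(sources).graph.number_of_edges() == 6

    def test_empty_union_errors(self):
        with pytest.raises(ValueError, match="empty network"):
            network.build_global_network([InteractionNetwork()])


def _expr(rows: dict, n: int) -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n)]).T


class TestCohortSpecificNetwork:
    def test_perfect_correlation_retained(self):
        x = np.arange(10.0)
        expr = _expr({"A": x, "B": 2 * x + 1}, 10)
        kept = network.cohort_specific_network(net_from_edges(("A", "B")), expr)
        assert kept.graph.has_edge("A", "B")

    def test_constant_endpoint_dropped(self):
        expr = _expr({"A": np.arange(10.0), "B": np.ones(10)}, 10)
        kept = network.cohort_specific_network(net_from_edges(("A", "B")), expr)
        assert kept.graph.number_of_edges() == 0

    def test_r_half_n50_retained(self):
        # construct vectors with empirical r exactly 0.5; oracle p from the
        # exact t transform: t = r sqrt((n-2)/(1-r^2)) = 0.5 * sqrt(48/0.75) = 4
        n = 50
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=n)
        z -= z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = 0.5 * x + math.sqrt(1 - 0.25) * z
        assert abs(np.corrcoef(x, y)[0, 1] - 0.5) < 1e-12
        from scipy import stats

        p_oracle = 2 * stats.t.sf(4.0, df=48)
        assert p_oracle < 0.05  # approx 2.1e-4
        expr = _expr({"A": x, "B": y}, n)
        kept = network.cohort_specific_network(net_from_edges(("A", "B")), expr)
        assert kept.graph.has_edge("A", "B")

    def test_too_few_samples_error(self):
        expr = _expr({"A": [1.0, 2.0], "B": [2.0, 1.0]}, 2)
        with pytest.raises(ValueError, match="3 samples"):
            network.cohort_specific_network(net_from_edges(("A", "B")), expr)

    def test_output_subset_and_monotone_in_r_min(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(20)]
        expr = pd.DataFrame(rng.normal(size=(20, 30)), index=genes)
        expr.columns = [f"s{i}" for i in range(30)]
        net = InteractionNetwork(nx.gnp_random_graph(20, 0.3, seed=4))
        net = InteractionNetwork(nx.relabel_nodes(net.graph, dict(enumerate(genes))))
        loose = network.cohort_specific_network(net, expr, r_min=0.1, p_max=0.8)
        tight = network.cohort_specific_network(net, expr, r_min=0.4, p_max=0.8)
        loose_edges = set(map(frozenset, loose.graph.edges))
        assert loose_edges <= set(map(frozenset, net.graph.edges))
        assert set(map(frozenset, tight.graph.edges)) <= loose_edges


class TestGenesetSubnetwork:
    def test_induced_subgraph(self):
        net = net_from_edges(("A", "B"), ("B", "D"))
        sub = network.geneset_subnetwork(net, ["A", "B", "C"])
        assert set(sub.nodes) == {"A", "B"}
        assert set(map(frozenset, sub.edges)) == {frozenset({"A", "B"})}

    def test_disjoint_set_gives_empty_subnetwork(self):
        sub = network.geneset_subnetwork(net_from_edges(("A", "B")), ["X", "Y"])
        assert sub.number_of_nodes() == 0

    def test_full_set_gives_whole_network(self):
        net = net_from_edges(("A", "B"), ("B", "C"))
        sub = network.geneset_subnetwork(net, ["A", "B", "C"])
        assert nx.utils.graphs_equal(sub, net.graph)


class TestCentralities:
    def test_path_graph_hand_values(self):
        table = network.centralities(nx.path_graph(["A", "B", "C"]))
        assert table.loc["B", "degree"] == 2
        assert table.loc["A", "degree"] == table.loc["C", "degree"] == 1
        assert table.loc["B", "betweenness"] == 1.0
        assert table.loc["A", "betweenness"] == table.loc["C", "betweenness"] == 0.0

    def test_isolated_node_all_zero(self):
        g = nx.Graph()
        g.add_node("X")
        table = network.centralities(g)
        assert tuple(table.loc["X"]) == (0.0, 0.0, 0.0)

    def test_star_center_maximizes_all_features(self):
        table = network.centralities(nx.star_graph(["hub", "a", "b", "c", "d"]))
        for feature in network.CENTRALITY_FEATURES:
            assert table[feature].idxmax() == "hub"
        oracle = oracles.brute_betweenness(nx.star_graph(["hub", "a", "b", "c", "d"]))
        assert table.loc["hub", "betweenness"] == pytest.approx(oracle["hub"])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_bruteforce_on_all_small_connected_graphs(self, n):
        for g in oracles.connected_graphs(n):
            table = network.centralities(g)
            deg = oracles.brute_degree(g)
            btw = oracles.brute_betweenness(g)
            for node in g.nodes:
                assert table.loc[node, "degree"] == deg[node]
                assert table.loc[node, "betweenness"] == pytest.approx(
                    btw[node], abs=1e-12
                )

    def test_eigenvector_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        graphs = [nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
                  for n in (5, 9, 14, 20) for p in (0.15, 0.4)]
        graphs.append(nx.disjoint_union(nx.path_graph(4), nx.cycle_graph(5)))
        for g in graphs:
            table = network.centralities(g)
            oracle = oracles.dense_eigenvector(g)
            for node in g.nodes:
                assert table.loc[node, "eigenvector"] == pytest.approx(
                    oracle[node], abs=1e-8
                )


class TestNormalize:
    def test_min_shift_sd_scale(self):
        raw = pd.DataFrame(
            {"degree": [1.0, 2.0, 3.0], "betweenness": [0.0] * 3, "eigenvector": [0.0] * 3},
            index=list("abc"),
        )
        out = network.normalize_centralities(raw)
        assert list(out["degree_n"]) == [0.0, 1.0, 2.0]

    def test_constant_feature_normalizes_to_zero(self):
        raw = pd.DataFrame(
            {"degree": [2.0, 2.0], "betweenness": [1.0, 3.0], "eigenvector": [0.5, 1.0]},
            index=list("ab"),
        )
        out = network.normalize_centralities(raw)
        assert list(out["degree_n"]) == [0.0, 0.0]
        assert out["betweenness_n"].min() == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=8),
        shift=st.integers(min_value=-5, max_value=5),
        scale=st.integers(min_value=1, max_value=4),
    )
    def test_shift_invariant_and_scale_equivariant(self, values, shift, scale):
        base = pd.DataFrame(
            {
                "degree": np.array(values, dtype=float),
                "betweenness": np.zeros(len(values)),
                "eigenvector": np.zeros(len(values)),
            }
        )
        shifted = base.copy()
        shifted["degree"] += shift
        scaled = base.copy()
        scaled["degree"] *= scale
        out = network.normalize_centralities(base)["degree_n"]
        assert np.allclose(
            network.normalize_centralities(shifted)["degree_n"], out, atol=1e-9
        )
        assert np.allclose(
            network.normalize_centralities(scaled)["degree_n"], out, atol=1e-9
        )
        assert out.min() == 0.0


def test_centrality_table_covers_in_network_set_genes(toy):
    table = network.centrality_table(toy.net, toy.sets)
    for name, genes in toy.sets.items():
        expected = {g for g in genes if g in toy.net.nodes}
        assert set(table[table["set"] == name]["gene"]) == expected
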