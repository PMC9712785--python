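import networkx as nx
import numpy as np
import pytest
from networkx.generators.atlas import graph_atlas_g

from spongenet.network import (
    SpongeNetwork,
    build_network,
    centralities,
    rank_hub_circrnas,
    restrict_to_de,
    select_key_mirnas,
)
from spongenet.records import DeRecord, InteractionEdge, RnaClass, ValidationError

from oracles import brute_betweenness, brute_closeness


def star_network(mirna_degrees: dict[str, int]) -> SpongeNetwork:
    """miRNA nodes wired to that many distinct circRNA partners."""
    edges = []
    counter = 0
    for mirna, degree in mirna_degrees.items():
        for _ in range(degree):
            edges.append(
                InteractionEdge(f"circ{counter}", RnaClass.CIRC, mirna, RnaClass.MIRNA,
                                sources={"sim"})
            )
            counter += 1
    return build_network(edges)


def random_sponge_edges(rng, n_circ=12, n_mirna=10, n_edges=30):
    pairs = {
        (f"circ{rng.integers(n_circ)}", f"miR-{rng.integers(n_mirna)}")
        for _ in range(n_edges)
    }
    return [
        InteractionEdge(c, RnaClass.CIRC, m, RnaClass.MIRNA, sources={"sim"})
        for c, m in sorted(pairs)
    ]


class TestBuildNetwork:
    def test_reference_hub_graph(self, hub_edges, circ_records, mirna_records):
        net = build_network(hub_edges, circ_records + mirna_records)
        assert net.n_nodes == 9
        assert net.n_edges == 6
        assert net.degree("circRNA00723") == 2
        assert net.direction("circRNA00723") == "down"
        assert net.direction("miR-6240") == "up"

    def test_empty_edge_list(self):
        assert build_network([]).n_nodes == 0

    def test_degree_sum_is_twice_edge_count(self, rng):
        for _ in range(20):
            net = build_network(random_sponge_edges(rng))
            degrees = [d for _, d in net.graph.degree()]
            assert sum(degrees) == 2 * net.n_edges

    def test_conflicting_node_class_rejected(self):
        edges = [
            InteractionEdge("a", RnaClass.CIRC, "b", RnaClass.MIRNA, sources={"s"}),
            InteractionEdge("b", RnaClass.MIRNA, "c", RnaClass.MRNA, sources={"s"}),
            InteractionEdge("c", RnaClass.CIRC, "a", RnaClass.MIRNA, sources={"s"}),
        ]
        with pytest.raises(ValidationError, match="both"):
            build_network(edges)


class TestRestrictToDe:
    def test_superset_is_identity(self, hub_edges):
        net = build_network(hub_edges)
        mirnas = set(net.nodes_of_class(RnaClass.MIRNA))
        assert restrict_to_de(net, mirnas | {"extra"}) == net

    def test_empty_set_removes_all_mirnas(self, hub_edges):
        net = restrict_to_de(build_network(hub_edges), set())
        assert net.nodes_of_class(RnaClass.MIRNA) == []
        assert net.n_edges == 0
        assert len(net.nodes_of_class(RnaClass.CIRC)) == 5  # kept, isolated

    def test_equals_filter_then_rebuild_oracle(self, rng):
        edges = random_sponge_edges(rng)
        net = build_network(edges)
        keep = {f"miR-{i}" for i in rng.choice(10, size=4, replace=False)}
        got = restrict_to_de(net, keep)
        rebuilt = build_network([e for e in edges if e.target_id in keep])
        # circRNAs always survive; miRNA/edge sets must match the rebuild
        assert set(got.nodes_of_class(RnaClass.MIRNA)) == set(
            rebuilt.nodes_of_class(RnaClass.MIRNA)
        )
        assert set(map(frozenset, got.graph.edges)) == set(
            map(frozenset, rebuilt.graph.edges)
        )
        assert set(got.nodes_of_class(RnaClass.CIRC)) == {e.source_id for e in edges}


class TestCentralities:
    def test_path_graph_closed_form(self):
        g = nx.Graph()
        for n, cls in [("a", "circRNA"), ("b", "miRNA"), ("c", "circRNA")]:
            g.add_node(n, rna_class=cls, direction=None)
        g.add_edge("a", "b"), g.add_edge("b", "c")
        net = centralities(SpongeNetwork(g))
        assert net.graph.nodes["b"]["betweenness"] == pytest.approx(1.0)
        assert net.graph.nodes["b"]["closeness"] == pytest.approx(1.0)
        assert net.graph.nodes["a"]["betweenness"] == 0.0

    def test_complete_graph_has_no_intermediates(self):
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, "mRNA", "rna_class")
        net = centralities(SpongeNetwork(g))
        assert all(net.graph.nodes[n]["betweenness"] == 0.0 for n in g)

    def test_isolated_node_gets_zeros(self):
        g = nx.Graph()
        g.add_node("lonely", rna_class="circRNA", direction=None)
        net = centralities(SpongeNetwork(g))
        assert net.graph.nodes["lonely"]["betweenness"] == 0.0
        assert net.graph.nodes["lonely"]["closeness"] == 0.0

    def test_all_atlas_graphs_up_to_six_nodes_match_brute_force(self):
        """Betweenness and closeness agree with an exhaustive all-shortest-
        paths oracle on every non-isomorphic graph with <= 6 nodes."""
        for g in graph_atlas_g():
            if g.number_of_nodes() > 6 or g.number_of_nodes() == 0:
                continue
            nx.set_node_attributes(g, "mRNA", "rna_class")
            net = centralities(SpongeNetwork(g))
            bet = brute_betweenness(g)
            clo = brute_closeness(g)
            for n in g:
                assert net.graph.nodes[n]["betweenness"] == pytest.approx(bet[n], abs=1e-12)
                assert net.graph.nodes[n]["closeness"] == pytest.approx(clo[n], abs=1e-12)


class TestSelectKeyMirnas:
    def test_single_high_degree_mirna_selected(self):
        net = star_network({"m1": 1, "m2": 1, "m3": 1, "m4": 1, "hub": 10})
        assert select_key_mirnas(net) == {"hub"}

    def test_uniform_degrees_select_nothing(self):
        net = star_network({f"m{i}": 3 for i in range(6)})
        assert select_key_mirnas(net) == set()

    def test_no_mirna_nodes_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no miRNA"):
            assert select_key_mirnas(SpongeNetwork()) == set()

    def test_selection_shrinks_as_multiplier_grows(self, rng):
        net = build_network(random_sponge_edges(rng, n_edges=40))
        previous = select_key_mirnas(net, multiplier=0.5)
        for multiplier in (1.0, 2.0, 3.0, 5.0):
            current = select_key_mirnas(net, multiplier=multiplier)
            assert current <= previous
            previous = current


class TestRankHubCircrnas:
    def test_single_circrna_returned_for_any_k(self, hub_edges):
        net = centralities(build_network(hub_edges[:1]))
        for k in (1, 3):
            assert [h for h, _ in rank_hub_circrnas(net, k=k)] == [hub_edges[0].source_id]

    def test_dominant_node_ranks_first(self):
        # hub sponges three miRNAs, spoke sponges one of them
        edges = [
            InteractionEdge("hub", RnaClass.CIRC, m, RnaClass.MIRNA, sources={"s"})
            for m in ("m1", "m2", "m3")
        ] + [InteractionEdge("spoke", RnaClass.CIRC, "m1", RnaClass.MIRNA, sources={"s"})]
        net = centralities(build_network(edges))
        ranked = rank_hub_circrnas(net, k=2)
        assert ranked[0][0] == "hub"

    def test_exclusion_consistency(self, rng):
        net = centralities(build_network(random_sponge_edges(rng, n_edges=40)))
        top3 = [h for h, _ in rank_hub_circrnas(net, k=3)]
        non_top = [c for c in net.nodes_of_class(RnaClass.CIRC) if c not in top3]
        if non_top:
            again = [h for h, _ in rank_hub_circrnas(net, exclude={non_top[0]}, k=3)]
            assert again == top3

    def test_matches_rank_combination_oracle(self, rng):
        for _ in range(15):
            net = centralities(build_network(random_sponge_edges(rng, 15, 15, 35)))
            circ = net.nodes_of_class(RnaClass.CIRC)
            got = [h for h, _ in rank_hub_circrnas(net, k=5)]
            # oracle: average of competition-free (average-tie) rank positions
            def ranks(values):
                out = {}
                ordered = sorted(values.items(), key=lambda kv: -kv[1])
                i = 0
                while i < len(ordered):
                    j = i
                    while j < len(ordered) and ordered[j][1] == ordered[i][1]:
                        j += 1
                    avg = (i + 1 + j) / 2
                    for name, _ in ordered[i:j]:
                        out[name] = avg
                    i = j
                return out
            bet = ranks({c: net.graph.nodes[c]["betweenness"] for c in circ})
            clo = ranks({c: net.graph.nodes[c]["closeness"] for c in circ})
            order = sorted(
                circ,
                key=lambda c: ((bet[c] + clo[c]) / 2, -net.graph.degree[c], c),
            )
            assert got == order[:5]

    def test_fewer_than_k_warns(self, hub_edges):
        net = centralities(build_network(hub_edges))
        with pytest.warns(UserWarning, match="eligible"):
            ranked = rank_hub_circrnas(net, k=10)
        assert len(ranked) == 5
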