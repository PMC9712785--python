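"""Sponge-network assembly, centralities and hub selection.

The circRNA-miRNA graph is undirected for centrality purposes.  Three node
importance measures drive the analysis: degree (incident edge count),
betweenness (fraction of all-pairs shortest paths passing through the node,
pair-normalized by 2/((n-1)(n-2))) and closeness in the Wasserman-Faust
within-component scaling, so that values remain comparable on disconnected
graphs.  Key miRNAs are the miRNA nodes whose degree strictly exceeds three
times the median miRNA degree; hub circRNAs are ranked by combining their
betweenness and closeness ranks.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .records import DeRecord, InteractionEdge, RnaClass, ValidationError

__all__ = [
    "SpongeNetwork",
    "build_network",
    "restrict_to_de",
    "centralities",
    "select_key_mirnas",
    "rank_hub_circrnas",
]


class SpongeNetwork:
    """Typed undirected graph of circRNA/miRNA/mRNA nodes.

    Thin wrapper over :class:`networkx.Graph`; node attributes are
    ``rna_class`` (string value of :class:`RnaClass`) and ``direction``
    (``"up"``/``"down"``/``None``), edge attributes ``sources`` and ``score``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- inspection -------------------------------------------------------
    def nodes_of_class(self, rna_class: RnaClass | str) -> list[str]:
        value = RnaClass.parse(rna_class).value
        return [n for n, d in self.graph.nodes(data=True) if d["rna_class"] == value]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def direction(self, node: str) -> str | None:
        return self.graph.nodes[node].get("direction")

    def copy(self) -> "SpongeNetwork":
        return SpongeNetwork(self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpongeNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and nx.utils.graphs_equal(self.graph, other.graph)
        )

    def node_table(self) -> pd.DataFrame:
        """Per-node metrics as a DataFrame (one row per node)."""
        rows = []
        for node, data in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "id": node,
                    "rna_class": data["rna_class"],
                    "direction": data.get("direction") or "",
                    "degree": self.graph.degree[node],
                    "betweenness": data.get("betweenness", float("nan")),
                    "closeness": data.get("closeness", float("nan")),
                }
            )
        return pd.DataFrame(
            rows, columns=["id", "rna_class", "direction", "degree", "betweenness", "closeness"]
        )


def build_network(
    edges: Iterable[InteractionEdge],
    de_annotations: Iterable[DeRecord] = (),
) -> SpongeNetwork:
    """Assemble the typed graph; nodes inherit direction from DE annotations.

    Raises :class:`ValidationError` if one identifier is used with two
    different RNA classes.
    """
    directions = {rec.feature_id: rec.direction.value for rec in de_annotations}
    graph = nx.Graph()

    def add_node(node_id: str, rna_class: RnaClass) -> None:
        existing = graph.nodes.get(node_id)
        if existing is not None and existing["rna_class"] != rna_class.value:
            raise ValidationError(
                f"node {node_id!r} used as both {existing['rna_class']} and {rna_class.value}"
            )
        graph.add_node(node_id, rna_class=rna_class.value, direction=directions.get(node_id))

    for edge in edges:
        add_node(edge.source_id, edge.source_class)
        add_node(edge.target_id, edge.target_class)
        graph.add_edge(edge.source_id, edge.target_id, sources=edge.sources, score=edge.score)
    return SpongeNetwork(graph)


def restrict_to_de(net: SpongeNetwork, de_ids: set[str]) -> SpongeNetwork:
    """Keep only miRNA nodes present in ``de_ids`` (with incident edges).

    circRNA and mRNA nodes are left intact even when they become isolated,
    so the caller can report how many sponges lost all their partners.
    """
    graph = net.graph.copy()
    drop = [
        n
        for n, d in graph.nodes(data=True)
        if d["rna_class"] == RnaClass.MIRNA.value and n not in de_ids
    ]
    graph.remove_nodes_from(drop)
    return SpongeNetwork(graph)


def centralities(net: SpongeNetwork) -> SpongeNetwork:
    """Annotate every node with degree, betweenness and closeness.

    Betweenness uses Brandes' algorithm with the standard 2/((n-1)(n-2))
    pair normalization; closeness uses the Wasserman-Faust variant
    (reachable-set fraction times inverse mean reachable distance), which
    handles disconnected graphs.  Isolated nodes get 0 for both.
    """
    graph = net.graph.copy()
    n = graph.number_of_nodes()
    betweenness = nx.betweenness_centrality(graph, normalized=n > 2)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    for node in graph.nodes:
        graph.nodes[node]["betweenness"] = betweenness[node]
        graph.nodes[node]["closeness"] = closeness[node]
    return SpongeNetwork(graph)


def select_key_mirnas(net: SpongeNetwork, multiplier: float = 3.0,
                      over_all_nodes: bool = False) -> set[str]:
    """miRNA nodes whose degree strictly exceeds ``multiplier`` x median degree.

    The median is computed over the degrees of miRNA nodes only (they are
    the selection population); set ``over_all_nodes`` to use every node's
    degree instead.
    """
    mirnas = net.nodes_of_class(RnaClass.MIRNA)
    if not mirnas:
        warnings.warn("network contains no miRNA nodes; empty key-miRNA set")
        return set()
    population = list(net.graph.nodes) if over_all_nodes else mirnas
    median = float(np.median([net.graph.degree[n] for n in population]))
    threshold = multiplier * median
    return {m for m in mirnas if net.graph.degree[m] > threshold}


def rank_hub_circrnas(
    net: SpongeNetwork,
    exclude: set[str] | None = None,
    k: int = 5,
) -> list[tuple[str, float]]:
    """Top-``k`` circRNA hubs by combined betweenness/closeness rank.

    Each eligible circRNA gets a rank position on betweenness and on
    closeness (1 = highest, average ranks on ties); candidates are ordered
    by the mean of the two ranks, with ties broken by higher degree and
    then lexicographic id.  ``exclude`` holds manually curated ids (e.g.
    already-reported candidates) removed from eligibility.  Returns
    (id, mean_rank) pairs, best first.
    """
    exclude = exclude or set()
    nodes = [n for n in net.nodes_of_class(RnaClass.CIRC) if n not in exclude]
    if not nodes:
        return []
    missing = [n for n in nodes if "betweenness" not in net.graph.nodes[n]]
    if missing:
        raise ValidationError("network lacks centrality annotations; run centralities() first")
    if len(nodes) < k:
        warnings.warn(f"only {len(nodes)} eligible circRNAs for top-{k} ranking")
    bet = np.array([net.graph.nodes[n]["betweenness"] for n in nodes])
    clo = np.array([net.graph.nodes[n]["closeness"] for n in nodes])
    # rankdata ranks ascending; negate so rank 1 = largest value
    mean_rank = (rankdata(-bet, method="average") + rankdata(-clo, method="average")) / 2.0
    order = sorted(
        range(len(nodes)),
        key=lambda i: (mean_rank[i], -net.graph.degree[nodes[i]], nodes[i]),
    )
    return [(nodes[i], float(mean_rank[i])) for i in order[:k]]
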