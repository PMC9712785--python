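"""Assembly of the final circRNA-miRNA-mRNA (ceRNA) network.

Starting from the hub circRNAs, the sponge edges are restricted to
(hub, differentially-expressed miRNA) pairs; each retained miRNA is then
expanded to its consensus mRNA targets, and triads are filtered for
direction consistency.  Under the competing-endogenous-RNA model a sponge
and the de-repressed mRNA should move together, opposite to the shared
miRNA — so the default filter requires the mRNA's direction to oppose the
miRNA's, while circRNA-miRNA opposition is recorded but not required
(observed sponge pairs include same-direction cases).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx

from .records import (
    CeRNATriad,
    DeRecord,
    Direction,
    InteractionEdge,
    RnaClass,
    dedupe_edges,
)
from .network import SpongeNetwork

__all__ = [
    "hub_mirna_edges",
    "expand_to_mrnas",
    "assemble_triads",
    "triads_to_network",
    "export_cerna",
]


def hub_mirna_edges(
    hubs: Iterable[str],
    edges: Iterable[InteractionEdge],
    de_mirnas: Iterable[str],
) -> list[InteractionEdge]:
    """Sponge edges restricted to (hub circRNA, DE miRNA) pairs, deduplicated."""
    hub_set, de_set = set(hubs), set(de_mirnas)
    kept = [
        e
        for e in edges
        if e.source_class is RnaClass.CIRC
        and e.source_id in hub_set
        and e.target_id in de_set
    ]
    return dedupe_edges(kept)


def expand_to_mrnas(
    mirna_ids: Iterable[str],
    mirna_mrna_edges: Iterable[InteractionEdge],
) -> dict[str, set[str]]:
    """Per-miRNA consensus mRNA target sets (empty set for targetless miRNAs)."""
    mapping: dict[str, set[str]] = {m: set() for m in mirna_ids}
    for edge in mirna_mrna_edges:
        if edge.source_class is RnaClass.MIRNA and edge.source_id in mapping:
            mapping[edge.source_id].add(edge.target_id)
    return mapping


def assemble_triads(
    hub_edges: Sequence[InteractionEdge],
    mirna_mrna_map: Mapping[str, set[str]],
    de_mrnas: Sequence[DeRecord] = (),
    require_opposite_mrna: bool = True,
    require_opposite_circ: bool = False,
    circ_directions: Mapping[str, Direction] | None = None,
    mirna_directions: Mapping[str, Direction] | None = None,
) -> list[CeRNATriad]:
    """Every (circ, miRNA, mRNA) combination along the hub edges and target map.

    With ``require_opposite_mrna`` (default) only triads whose mRNA is
    differentially expressed in the direction opposite to the miRNA are
    kept; mRNAs absent from ``de_mrnas`` carry direction ``None`` and are
    dropped by that filter.  ``require_opposite_circ`` additionally demands
    circRNA-miRNA opposition (off by default).
    """
    circ_dir = dict(circ_directions or {})
    mirna_dir = dict(mirna_directions or {})
    mrna_dir = {rec.feature_id: rec.direction for rec in de_mrnas}

    triads: list[CeRNATriad] = []
    for edge in hub_edges:
        circ, mirna = edge.source_id, edge.target_id
        for mrna in sorted(mirna_mrna_map.get(mirna, ())):
            triad = CeRNATriad(
                circ_id=circ,
                circ_direction=circ_dir.get(circ),
                mirna_id=mirna,
                mirna_direction=mirna_dir.get(mirna),
                mrna_id=mrna,
                mrna_direction=mrna_dir.get(mrna),
            )
            if require_opposite_mrna and not triad.mirna_mrna_opposite:
                continue
            if require_opposite_circ and not triad.circ_mirna_opposite:
                continue
            triads.append(triad)
    return triads


def triads_to_network(
    triads: Sequence[CeRNATriad],
    extra_mrnas: Mapping[str, set[str]] | None = None,
) -> SpongeNetwork:
    """Tripartite network of the triads; ``extra_mrnas`` adds the non-DE
    targets kept in the exported network but excluded from triad statistics."""
    graph = nx.Graph()

    def _dir(direction: Direction | None) -> str | None:
        return direction.value if direction is not None else None

    for t in triads:
        graph.add_node(t.circ_id, rna_class=RnaClass.CIRC.value, direction=_dir(t.circ_direction))
        graph.add_node(t.mirna_id, rna_class=RnaClass.MIRNA.value, direction=_dir(t.mirna_direction))
        graph.add_node(t.mrna_id, rna_class=RnaClass.MRNA.value, direction=_dir(t.mrna_direction))
        graph.add_edge(t.circ_id, t.mirna_id, sources=frozenset({"sponge"}), score=None)
        graph.add_edge(t.mirna_id, t.mrna_id, sources=frozenset({"target"}), score=None)
    if extra_mrnas:
        for mirna, mrnas in extra_mrnas.items():
            if mirna not in graph:
                continue
            for mrna in sorted(mrnas):
                if mrna not in graph:
                    graph.add_node(mrna, rna_class=RnaClass.MRNA.value, direction=None)
                graph.add_edge(mirna, mrna, sources=frozenset({"target"}), score=None)
    return SpongeNetwork(graph)


def export_cerna(
    triads: Sequence[CeRNATriad],
    path,
    dialect: str = "GraphML",
    extra_mrnas: Mapping[str, set[str]] | None = None,
) -> SpongeNetwork:
    """Write the tripartite ceRNA network and return it."""
    from .io import write_network

    net = triads_to_network(triads, extra_mrnas=extra_mrnas)
    write_network(net, path, dialect=dialect)
    return net
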