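"""Readers and writers for every external format the pipeline touches.

Tables are tab-separated by default; a comma delimiter is accepted by
sniffing the header line.  Decimal points only; scientific notation
(``9.38E-09``) is accepted.  Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    AnnotationSet,
    CtTable,
    DeRecord,
    Direction,
    FormatError,
    InteractionEdge,
    Namespace,
    RnaClass,
    ValidationError,
    dedupe_edges,
)
from .network import SpongeNetwork

__all__ = [
    "read_de_table",
    "write_de_table",
    "read_edge_list",
    "write_edge_list",
    "read_network",
    "write_network",
    "read_gmt",
    "read_ct_table",
    "write_ct_table",
    "read_fasta",
    "write_fasta",
]

_ID_ALIASES = {"id", "featureid", "feature", "name", "circrnas", "mirnas", "mrnas", "gene"}
_LFC_ALIASES = {"log2fc", "log2foldchange", "logfc", "log2fold"}
_P_ALIASES = {"pvalue", "p", "pval"}
_REG_ALIASES = {"regulation", "direction"}
_EXTRA_ALIASES = {
    "gc_percent": {"gcpercent", "gc", "gccontent"},
    "circ_type": {"circtype", "type", "circrnastype"},
    "length_nt": {"lengthnt", "length", "len"},
    "chromosome": {"chromosome", "chr", "chrom"},
}


def _norm(column: str) -> str:
    return "".join(ch for ch in column.lower() if ch.isalnum())


def _sniff_sep(path: Path) -> str:
    with open(path) as handle:
        header = handle.readline()
    return "\t" if "\t" in header else ","


def read_de_table(path: str | Path, rna_class: RnaClass | str) -> list[DeRecord]:
    """Parse a differential-expression table into :class:`DeRecord` rows.

    Required columns (by any common alias): feature id, log2 fold change and
    p-value.  A ``regulation`` column, when present, must agree with the sign
    of the fold change; otherwise the direction is derived from the sign.
    """
    path = Path(path)
    rna_class = RnaClass.parse(rna_class)
    frame = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    cols: dict[str, str] = {}
    for col in frame.columns:
        key = _norm(str(col))
        if key in _ID_ALIASES:
            cols.setdefault("id", col)
        elif key in _LFC_ALIASES:
            cols.setdefault("log2fc", col)
        elif key in _P_ALIASES:
            cols.setdefault("p_value", col)
        elif key in _REG_ALIASES:
            cols.setdefault("regulation", col)
        else:
            for extra, aliases in _EXTRA_ALIASES.items():
                if key in aliases:
                    cols.setdefault(extra, col)
    for mandatory in ("id", "log2fc", "p_value"):
        if mandatory not in cols:
            raise FormatError(f"{path.name}: missing mandatory column {mandatory!r}")

    records: list[DeRecord] = []
    for idx, row in frame.iterrows():
        extras = {
            key: row[cols[key]]
            for key in _EXTRA_ALIASES
            if key in cols and not pd.isna(row[cols[key]])
        }
        if "length_nt" in extras:
            extras["length_nt"] = int(extras["length_nt"])
        direction = None
        if "regulation" in cols and not pd.isna(row[cols["regulation"]]):
            direction = Direction.parse(row[cols["regulation"]])
        try:
            records.append(
                DeRecord(
                    feature_id=str(row[cols["id"]]),
                    rna_class=rna_class,
                    log2fc=float(row[cols["log2fc"]]),
                    p_value=float(row[cols["p_value"]]),
                    direction=direction,
                    extras=extras,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path.name} row {idx + 2}: {err}") from None
    return records


def write_de_table(records: Sequence[DeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "feature_id": rec.feature_id,
            "log2fc": rec.log2fc,
            "p_value": rec.p_value,
            "regulation": rec.direction.value.capitalize(),
        }
        row.update(rec.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _infer_class(feature_id: str) -> RnaClass:
    lowered = feature_id.lower()
    if lowered.startswith("circ"):
        return RnaClass.CIRC
    if lowered.startswith(("mir", "mmu-mir", "let-")):
        return RnaClass.MIRNA
    return RnaClass.MRNA


def read_edge_list(
    path: str | Path,
    source_class: RnaClass | str | None = None,
    target_class: RnaClass | str | None = None,
) -> list[InteractionEdge]:
    """Parse an interaction edge list (database export or predictor output).

    Expects columns ``source`` and ``target`` plus optional evidence-label
    and score columns.  Repeated pairs are merged with their evidence labels
    unioned.  Node classes are taken from the arguments when given,
    otherwise inferred from the identifier prefix (``circ…`` -> circRNA,
    ``miR…``/``let-…`` -> miRNA, anything else -> mRNA).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    cols = {_norm(str(c)): c for c in frame.columns}
    src_col = cols.get("source") or cols.get("sourceid")
    tgt_col = cols.get("target") or cols.get("targetid")
    if src_col is None or tgt_col is None:
        raise FormatError(f"{path.name}: need 'source' and 'target' columns")
    label_col = cols.get("evidence") or cols.get("sources") or cols.get("database")
    score_col = cols.get("score")

    edges: list[InteractionEdge] = []
    for idx, row in frame.iterrows():
        src, tgt = str(row[src_col]), str(row[tgt_col])
        s_cls = RnaClass.parse(source_class) if source_class else _infer_class(src)
        t_cls = RnaClass.parse(target_class) if target_class else _infer_class(tgt)
        labels = (
            frozenset(str(row[label_col]).split("|"))
            if label_col and not pd.isna(row[label_col])
            else frozenset({path.stem})
        )
        score = None
        if score_col and not pd.isna(row[score_col]):
            score = float(row[score_col])
        try:
            edges.append(
                InteractionEdge(src, s_cls, tgt, t_cls, sources=labels, score=score)
            )
        except ValidationError as err:
            raise ValidationError(f"{path.name} row {idx + 2}: {err}") from None
    return dedupe_edges(edges)


def write_edge_list(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    rows = [
        {
            "source": e.source_id,
            "source_class": e.source_class.value,
            "target": e.target_id,
            "target_class": e.target_class.value,
            "evidence": "|".join(sorted(e.sources)),
            "score": "" if e.score is None else e.score,
        }
        for e in edges
    ]
    pd.DataFrame(
        rows, columns=["source", "source_class", "target", "target_class", "evidence", "score"]
    ).to_csv(path, sep="\t", index=False)


_DIALECTS = ("SIF", "GraphML", "edge_tsv")


def write_network(net: SpongeNetwork, path: str | Path, dialect: str = "edge_tsv") -> None:
    """Serialize a network for Cytoscape interop (SIF/GraphML) or as TSV.

    GraphML and edge_tsv round-trip node classes, directions and edges
    exactly.  SIF carries node classes on the interaction label, so the
    class of an isolated node is re-inferred from its id prefix on read.
    """
    path = Path(path)
    graph = net.graph
    if dialect == "SIF":
        with open(path, "w") as handle:
            written = set()
            for u, v in sorted(graph.edges()):
                label = f"{graph.nodes[u]['rna_class']}-{graph.nodes[v]['rna_class']}"
                handle.write(f"{u}\t{label}\t{v}\n")
                written.update((u, v))
            for node in sorted(set(graph.nodes()) - written):
                handle.write(f"{node}\n")
    elif dialect == "GraphML":
        export = nx.Graph()
        for node, data in graph.nodes(data=True):
            export.add_node(
                node,
                rna_class=data["rna_class"],
                direction=data.get("direction") or "",
            )
        for u, v, data in graph.edges(data=True):
            export.add_edge(
                u,
                v,
                sources="|".join(sorted(data.get("sources", ()))),
                score=float("nan") if data.get("score") is None else float(data["score"]),
            )
        nx.write_graphml(export, path)
    elif dialect == "edge_tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(["#node", "id", "rna_class", "direction"])
            for node, data in sorted(graph.nodes(data=True)):
                writer.writerow(["node", node, data["rna_class"], data.get("direction") or ""])
            writer.writerow(["#edge", "source", "target", "evidence", "score"])
            for u, v, data in sorted(graph.edges(data=True)):
                score = data.get("score")
                writer.writerow(
                    [
                        "edge",
                        u,
                        v,
                        "|".join(sorted(data.get("sources", ()))),
                        "" if score is None else score,
                    ]
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")


def read_network(path: str | Path, dialect: str = "edge_tsv") -> SpongeNetwork:
    path = Path(path)
    graph = nx.Graph()
    if dialect == "SIF":
        with open(path) as handle:
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    graph.add_node(parts[0], rna_class=_infer_class(parts[0]).value, direction=None)
                elif len(parts) >= 3:
                    u, label, v = parts[0], parts[1], parts[2]
                    u_cls, _, v_cls = label.partition("-")
                    graph.add_node(u, rna_class=u_cls, direction=None)
                    graph.add_node(v, rna_class=v_cls, direction=None)
                    graph.add_edge(u, v, sources=frozenset(), score=None)
    elif dialect == "GraphML":
        raw = nx.read_graphml(path)
        for node, data in raw.nodes(data=True):
            graph.add_node(
                node,
                rna_class=data["rna_class"],
                direction=data.get("direction") or None,
            )
        for u, v, data in raw.edges(data=True):
            score = data.get("score")
            if score is not None and math.isnan(score):
                score = None
            sources = frozenset(data["sources"].split("|")) if data.get("sources") else frozenset()
            graph.add_edge(u, v, sources=sources, score=score)
    elif dialect == "edge_tsv":
        with open(path) as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "node":
                    graph.add_node(row[1], rna_class=row[2], direction=row[3] or None)
                elif row[0] == "edge":
                    sources = frozenset(row[3].split("|")) if row[3] else frozenset()
                    score = float(row[4]) if row[4] else None
                    graph.add_edge(row[1], row[2], sources=sources, score=score)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    return SpongeNetwork(graph)


def read_gmt(path: str | Path, namespace: Namespace | str = Namespace.PATHWAY) -> list[AnnotationSet]:
    """Parse a GMT file (term, description, members...) into annotation sets.

    Lines with an empty member list are skipped with a warning.
    """
    namespace = Namespace(namespace)
    sets: list[AnnotationSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"GMT line {lineno}: fewer than two fields")
            term_id, term_name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                warnings.warn(f"GMT line {lineno} ({term_id}): empty member list, skipped")
                continue
            sets.append(AnnotationSet(term_id, term_name, namespace, members))
    return sets


def read_ct_table(path: str | Path) -> CtTable:
    path = Path(path)
    return CtTable(pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip"))


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
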