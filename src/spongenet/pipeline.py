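"""End-to-end ceRNA network inference as a model/results pair.

:class:`CeRNANetworkModel` bundles the pipeline inputs (differential-
expression evidence for the three RNA classes, sponge and targeting edges,
optional annotation sets and qPCR table) together with the analysis
choices (screening rule, hub count, exclusion list).  ``fit()`` runs

    screen -> sponge network -> DE restriction -> centralities ->
    key miRNAs -> hub circRNAs -> hub-miRNA edges -> mRNA expansion ->
    triad assembly [-> enrichment] [-> qPCR quantification]

and returns a :class:`CeRNAResults` carrying every intermediate, the stage
counts and a ``summary()`` table.  :func:`run_pipeline` is the file-based
front end: it reads a YAML configuration (or simulates inputs), fits the
model and writes all intermediates plus a manifest to a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .records import CeRNATriad, DeRecord, Direction, InteractionEdge, RnaClass
from .screening import ScreeningRule, de_test_matrix, screen, summarize_screened
from .network import (
    SpongeNetwork,
    build_network,
    centralities,
    rank_hub_circrnas,
    restrict_to_de,
    select_key_mirnas,
)
from .cerna import assemble_triads, expand_to_mrnas, hub_mirna_edges, triads_to_network
from .enrichment import EnrichmentResult, run_ora
from .qpcr import FoldChangeResult, quantify_genes
from .records import AnnotationSet, CtTable

logger = logging.getLogger("spongenet")

__all__ = ["CeRNANetworkModel", "CeRNAResults", "run_pipeline"]


@dataclass
class CeRNAResults:
    """Fitted pipeline state: screened sets, networks, hubs, triads, stats."""

    rule: ScreeningRule
    screened: dict[RnaClass, list[DeRecord]]
    sponge_full: SpongeNetwork
    sponge_de: SpongeNetwork
    n_overlap_mirnas: int
    key_mirnas: set[str]
    hubs: list[tuple[str, float]]
    hub_edges: list[InteractionEdge]
    mirna_mrna_map: dict[str, set[str]]
    triads: list[CeRNATriad]
    cerna_network: SpongeNetwork
    counts_log: dict[str, int]
    enrichment: list[EnrichmentResult] = field(default_factory=list)
    qpcr: list[FoldChangeResult] = field(default_factory=list)

    @property
    def hub_ids(self) -> list[str]:
        return [h for h, _ in self.hubs]

    @property
    def mrna_union(self) -> set[str]:
        return set().union(*self.mirna_mrna_map.values()) if self.mirna_mrna_map else set()

    def screening_summary(self, rna_class: RnaClass) -> dict:
        return summarize_screened(self.screened[rna_class])

    def triad_table(self) -> pd.DataFrame:
        rows = [
            {
                "circ_id": t.circ_id,
                "circ_direction": t.circ_direction.value if t.circ_direction else "",
                "mirna_id": t.mirna_id,
                "mirna_direction": t.mirna_direction.value if t.mirna_direction else "",
                "mrna_id": t.mrna_id,
                "mrna_direction": t.mrna_direction.value if t.mrna_direction else "",
                "circ_mirna_opposite": t.circ_mirna_opposite,
                "mirna_mrna_opposite": t.mirna_mrna_opposite,
            }
            for t in self.triads
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "circ_id", "circ_direction", "mirna_id", "mirna_direction",
                "mrna_id", "mrna_direction", "circ_mirna_opposite", "mirna_mrna_opposite",
            ],
        )

    def summary(self) -> str:
        lines = ["ceRNA network inference", "=" * 47]
        for rna_class in (RnaClass.CIRC, RnaClass.MIRNA, RnaClass.MRNA):
            s = self.screening_summary(rna_class)
            lines.append(
                f"DE {rna_class.value:<7}: {s['n']:>5} kept "
                f"({s['n_up']} up / {s['n_down']} down)"
            )
        lines += [
            f"sponge network          : {self.sponge_full.n_nodes} nodes, "
            f"{self.sponge_full.n_edges} edges",
            f"DE-restricted network   : {self.sponge_de.n_nodes} nodes, "
            f"{self.sponge_de.n_edges} edges "
            f"({self.n_overlap_mirnas} overlapping miRNAs)",
            f"key miRNAs (deg>3*med)  : {len(self.key_mirnas)}",
            f"hub circRNAs            : {', '.join(self.hub_ids) or '(none)'}",
            f"hub-miRNA sponge edges  : {len(self.hub_edges)}",
            f"consensus target mRNAs  : {len(self.mrna_union)}",
            f"direction-consistent triads: {len(self.triads)}",
            f"ceRNA network           : {self.cerna_network.n_nodes} nodes, "
            f"{self.cerna_network.n_edges} edges",
        ]
        if self.enrichment:
            lines.append(f"enriched terms reported : {len(self.enrichment)}")
        if self.qpcr:
            lines.append(f"qPCR genes quantified   : {len(self.qpcr)}")
        return "\n".join(lines)


class CeRNANetworkModel:
    """ceRNA sponge-network inference over DE tables and interaction edges.

    Parameters
    ----------
    de_circ, de_mirna, de_mrna
        Full (pre-screening) differential-expression records per class.
    circ_mirna_edges
        Predicted or database-derived sponge edges (circRNA -> miRNA).
    mirna_mrna_edges
        Consensus targeting edges (miRNA -> mRNA).
    rule
        Screening thresholds; default |log2FC| >= 1 and p < 0.05.
    hub_top_k
        Number of hub circRNAs to rank; ``None`` keeps every eligible one
        (used by recovery benchmarks where ranking is reporting, not a
        filter).
    exclude_hubs
        Manually curated circRNA ids removed from hub eligibility (e.g.
        already reported in the disease literature).
    require_opposite_mrna / require_opposite_circ
        Direction-consistency filters for triad assembly.
    annotation_sets / ct_table
        Optional enrichment collections and qPCR cycle thresholds.
    """

    def __init__(
        self,
        de_circ: Sequence[DeRecord],
        de_mirna: Sequence[DeRecord],
        de_mrna: Sequence[DeRecord],
        circ_mirna_edges: Sequence[InteractionEdge],
        mirna_mrna_edges: Sequence[InteractionEdge],
        rule: ScreeningRule | None = None,
        hub_top_k: int | None = 5,
        exclude_hubs: set[str] | None = None,
        key_mirna_multiplier: float = 3.0,
        require_opposite_mrna: bool = True,
        require_opposite_circ: bool = False,
        annotation_sets: Sequence[AnnotationSet] = (),
        ct_table: CtTable | None = None,
    ):
        self.de_circ = list(de_circ)
        self.de_mirna = list(de_mirna)
        self.de_mrna = list(de_mrna)
        self.circ_mirna_edges = list(circ_mirna_edges)
        self.mirna_mrna_edges = list(mirna_mrna_edges)
        self.rule = rule or ScreeningRule()
        self.hub_top_k = hub_top_k
        self.exclude_hubs = set(exclude_hubs or ())
        self.key_mirna_multiplier = key_mirna_multiplier
        self.require_opposite_mrna = require_opposite_mrna
        self.require_opposite_circ = require_opposite_circ
        self.annotation_sets = list(annotation_sets)
        self.ct_table = ct_table

    @classmethod
    def from_dataframes(
        cls,
        de_circ: pd.DataFrame,
        de_mirna: pd.DataFrame,
        de_mrna: pd.DataFrame,
        circ_mirna_edges: pd.DataFrame,
        mirna_mrna_edges: pd.DataFrame,
        **kwargs,
    ) -> "CeRNANetworkModel":
        """Build from in-memory DataFrames with the same columns as the TSVs."""
        import io as _io
        from .io import read_de_table, read_edge_list
        import tempfile, os

        def _via_tsv(frame: pd.DataFrame, reader, *args, **kw):
            with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as tmp:
                frame.to_csv(tmp, sep="\t", index=False)
                name = tmp.name
            try:
                return reader(name, *args, **kw)
            finally:
                os.unlink(name)

        return cls(
            _via_tsv(de_circ, read_de_table, RnaClass.CIRC),
            _via_tsv(de_mirna, read_de_table, RnaClass.MIRNA),
            _via_tsv(de_mrna, read_de_table, RnaClass.MRNA),
            _via_tsv(circ_mirna_edges, read_edge_list, RnaClass.CIRC, RnaClass.MIRNA),
            _via_tsv(mirna_mrna_edges, read_edge_list, RnaClass.MIRNA, RnaClass.MRNA),
            **kwargs,
        )

    def fit(self) -> CeRNAResults:
        counts_log: dict[str, int] = {}
        screened = {
            RnaClass.CIRC: screen(self.de_circ, self.rule),
            RnaClass.MIRNA: screen(self.de_mirna, self.rule),
            RnaClass.MRNA: screen(self.de_mrna, self.rule),
        }
        for rna_class, kept in screened.items():
            counts_log[f"de_{rna_class.value}"] = len(kept)
            logger.info("screening %s: %d of %d kept", rna_class.value, len(kept),
                        len(getattr(self, f"de_{'circ' if rna_class is RnaClass.CIRC else 'mirna' if rna_class is RnaClass.MIRNA else 'mrna'}")))
        de_annotations = screened[RnaClass.CIRC] + screened[RnaClass.MIRNA] + screened[RnaClass.MRNA]

        # sponge edges whose circRNA survived screening
        screened_circ_ids = {r.feature_id for r in screened[RnaClass.CIRC]}
        sponge_edges = [e for e in self.circ_mirna_edges if e.source_id in screened_circ_ids]
        sponge_full = build_network(sponge_edges, de_annotations)
        counts_log["sponge_edges"] = sponge_full.n_edges
        counts_log["sponge_mirnas"] = len(sponge_full.nodes_of_class(RnaClass.MIRNA))
        logger.info("sponge network: %d interactions, %d circRNAs, %d miRNAs",
                    sponge_full.n_edges,
                    len(sponge_full.nodes_of_class(RnaClass.CIRC)),
                    counts_log["sponge_mirnas"])

        de_mirna_ids = {r.feature_id for r in screened[RnaClass.MIRNA]}
        sponge_de = restrict_to_de(sponge_full, de_mirna_ids)
        n_overlap = len(sponge_de.nodes_of_class(RnaClass.MIRNA))
        counts_log["overlap_mirnas"] = n_overlap
        logger.info("DE-miRNA intersection: %d overlapping miRNAs", n_overlap)

        sponge_de = centralities(sponge_de)
        key_mirnas = select_key_mirnas(sponge_de, multiplier=self.key_mirna_multiplier)
        counts_log["key_mirnas"] = len(key_mirnas)
        k = self.hub_top_k
        if k is None:
            k = len(sponge_de.nodes_of_class(RnaClass.CIRC))
        hubs = rank_hub_circrnas(sponge_de, exclude=self.exclude_hubs, k=k)
        logger.info("hub circRNAs: %s", [h for h, _ in hubs])

        hub_edges = hub_mirna_edges([h for h, _ in hubs], sponge_edges, de_mirna_ids)
        counts_log["hub_edges"] = len(hub_edges)
        hub_mirna_ids = sorted({e.target_id for e in hub_edges})
        mirna_mrna_map = expand_to_mrnas(hub_mirna_ids, self.mirna_mrna_edges)
        union = set().union(*mirna_mrna_map.values()) if mirna_mrna_map else set()
        counts_log["target_mrnas"] = len(union)
        logger.info("hub edges: %d over %d miRNAs; %d consensus target mRNAs",
                    len(hub_edges), len(hub_mirna_ids), len(union))

        circ_dirs = {r.feature_id: r.direction for r in screened[RnaClass.CIRC]}
        mirna_dirs = {r.feature_id: r.direction for r in screened[RnaClass.MIRNA]}
        triads = assemble_triads(
            hub_edges,
            mirna_mrna_map,
            de_mrnas=screened[RnaClass.MRNA],
            require_opposite_mrna=self.require_opposite_mrna,
            require_opposite_circ=self.require_opposite_circ,
            circ_directions=circ_dirs,
            mirna_directions=mirna_dirs,
        )
        counts_log["triads"] = len(triads)
        cerna_network = triads_to_network(triads, extra_mrnas=mirna_mrna_map)
        # hub sponge edges stay in the exported network even if filtered from triads
        for edge in hub_edges:
            cerna_network.graph.add_node(
                edge.source_id, rna_class=RnaClass.CIRC.value,
                direction=circ_dirs.get(edge.source_id).value if circ_dirs.get(edge.source_id) else None)
            cerna_network.graph.add_node(
                edge.target_id, rna_class=RnaClass.MIRNA.value,
                direction=mirna_dirs.get(edge.target_id).value if mirna_dirs.get(edge.target_id) else None)
            cerna_network.graph.add_edge(
                edge.source_id, edge.target_id, sources=frozenset({"sponge"}), score=None)
        counts_log["cerna_nodes"] = cerna_network.n_nodes
        counts_log["cerna_edges"] = cerna_network.n_edges
        logger.info("ceRNA network: %d nodes, %d edges, %d triads",
                    cerna_network.n_nodes, cerna_network.n_edges, len(triads))

        enrichment_results: list[EnrichmentResult] = []
        if self.annotation_sets and union:
            enrichment_results = run_ora(union, self.annotation_sets)
        qpcr_results: list[FoldChangeResult] = []
        if self.ct_table is not None:
            qpcr_results = quantify_genes(self.ct_table)

        return CeRNAResults(
            rule=self.rule,
            screened=screened,
            sponge_full=sponge_full,
            sponge_de=sponge_de,
            n_overlap_mirnas=n_overlap,
            key_mirnas=key_mirnas,
            hubs=hubs,
            hub_edges=hub_edges,
            mirna_mrna_map=mirna_mrna_map,
            triads=triads,
            cerna_network=cerna_network,
            counts_log=counts_log,
            enrichment=enrichment_results,
            qpcr=qpcr_results,
        )


# ---------------------------------------------------------------------------
# file-based front end


def _load_model_from_config(config: Mapping, base: Path) -> tuple[CeRNANetworkModel, dict | None]:
    """Build a model from a parsed YAML config; returns (model, recovery_info)."""
    from .io import read_ct_table, read_de_table, read_edge_list, read_gmt
    from .simulate import SimulationConfig, simulate_all
    from .targets import predict_interactions

    rule_cfg = config.get("screening", {})
    rule = ScreeningRule(
        min_abs_log2fc=float(rule_cfg.get("min_abs_log2fc", 1.0)),
        max_p=float(rule_cfg.get("max_p", 0.05)),
        adjust_p=bool(rule_cfg.get("adjust_p", False)),
    )
    options = dict(
        rule=rule,
        hub_top_k=config.get("hub_top_k", 5),
        exclude_hubs=set(config.get("exclude_hubs", ())),
        key_mirna_multiplier=float(config.get("key_mirna_multiplier", 3.0)),
        require_opposite_mrna=bool(config.get("require_opposite_mrna", True)),
        require_opposite_circ=bool(config.get("require_opposite_circ", False)),
    )

    if "simulate" in config:
        sim_kwargs = dict(config["simulate"] or {})
        if "seed" in config:
            sim_kwargs.setdefault("seed", int(config["seed"]))
        cfg = SimulationConfig(**sim_kwargs)
        matrices, mirna_seqs, target_seqs, ct, truth = simulate_all(cfg)
        case = [s for s in cfg.samples if s.startswith("case")]
        control = [s for s in cfg.samples if s.startswith("control")]
        de_tables = {
            rna_class: de_test_matrix(matrix, case, control, rna_class)
            for rna_class, matrix in matrices.items()
        }
        circ_ids = set(matrices[RnaClass.CIRC].index)
        circ_seqs = {t: s for t, s in target_seqs.items() if t in circ_ids}
        mrna_seqs = {t: s for t, s in target_seqs.items() if t not in circ_ids}
        pred = config.get("prediction", {})
        sponge_edges = predict_interactions(
            mirna_seqs, circ_seqs, RnaClass.CIRC,
            policy=pred.get("circ_policy", "union"),
            min_score=float(pred.get("min_score", 2.0)),
        )
        target_edges = predict_interactions(
            mirna_seqs, mrna_seqs, RnaClass.MRNA,
            policy=pred.get("mrna_policy", "intersection"),
            min_score=float(pred.get("min_score", 2.0)),
        )
        model = CeRNANetworkModel(
            de_tables[RnaClass.CIRC], de_tables[RnaClass.MIRNA], de_tables[RnaClass.MRNA],
            sponge_edges, target_edges, ct_table=ct, **options,
        )
        return model, {"truth": truth, "cfg": cfg}

    inputs = config["inputs"]

    def _path(key: str) -> Path:
        return base / inputs[key]

    de_circ = read_de_table(_path("de_circ"), RnaClass.CIRC)
    de_mirna = read_de_table(_path("de_mirna"), RnaClass.MIRNA)
    de_mrna = (
        read_de_table(_path("de_mrna"), RnaClass.MRNA) if "de_mrna" in inputs else []
    )
    sponge_edges = read_edge_list(_path("circ_mirna_edges"), RnaClass.CIRC, RnaClass.MIRNA)
    target_edges = (
        read_edge_list(_path("mirna_mrna_edges"), RnaClass.MIRNA, RnaClass.MRNA)
        if "mirna_mrna_edges" in inputs
        else []
    )
    annotation_sets = read_gmt(_path("gmt")) if "gmt" in inputs else []
    ct_table = read_ct_table(_path("ct_table")) if "ct_table" in inputs else None
    model = CeRNANetworkModel(
        de_circ, de_mirna, de_mrna, sponge_edges, target_edges,
        annotation_sets=annotation_sets, ct_table=ct_table, **options,
    )
    return model, None


def _recovery_report(results: CeRNAResults, truth) -> dict:
    """Planted-signal recovery: per-class screening metrics and triad recall."""
    report: dict = {}
    for rna_class in (RnaClass.CIRC, RnaClass.MIRNA, RnaClass.MRNA):
        planted = truth.de_ids(rna_class)
        called = {r.feature_id for r in results.screened[rna_class]}
        tp = len(planted & called)
        report[f"sensitivity_{rna_class.value}"] = tp / len(planted) if planted else float("nan")
        report[f"precision_{rna_class.value}"] = tp / len(called) if called else float("nan")
    graph = results.cerna_network.graph
    recovered = sum(
        1
        for circ, mirna, mrna in truth.triads
        if graph.has_edge(circ, mirna) and graph.has_edge(mirna, mrna)
    )
    report["triad_recall"] = recovered / len(truth.triads) if truth.triads else float("nan")
    report["n_chance_sites"] = len(truth.chance_sites)
    return report


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> Path:
    """Execute the full pipeline from a YAML config and write a run directory.

    The config either names input files under ``inputs:`` or carries a
    ``simulate:`` block with :class:`~spongenet.simulate.SimulationConfig`
    fields.  Every intermediate table, the final networks, a summary report
    and a manifest (config hash, seed, package version) are written under
    ``out_dir``.
    """
    from .io import write_de_table, write_edge_list, write_network

    if isinstance(config, (str, Path)):
        config_path = Path(config)
        config_text = config_path.read_text()
        config_data = yaml.safe_load(config_text)
        base = config_path.parent
    else:
        config_data = dict(config)
        config_text = yaml.safe_dump(config_data, sort_keys=True)
        base = Path(".")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, sim_info = _load_model_from_config(config_data, base)
    results = model.fit()

    for rna_class in (RnaClass.CIRC, RnaClass.MIRNA, RnaClass.MRNA):
        write_de_table(results.screened[rna_class], out / f"screened_{rna_class.value}.tsv")
    write_network(results.sponge_full, out / "sponge_network.tsv", "edge_tsv")
    write_network(results.sponge_de, out / "sponge_network_de.tsv", "edge_tsv")
    results.sponge_de.node_table().to_csv(out / "node_metrics.tsv", sep="\t", index=False)
    (out / "key_mirnas.txt").write_text("".join(f"{m}\n" for m in sorted(results.key_mirnas)))
    pd.DataFrame(results.hubs, columns=["circ_id", "mean_rank"]).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    write_edge_list(results.hub_edges, out / "hub_edges.tsv")
    results.triad_table().to_csv(out / "triads.tsv", sep="\t", index=False)
    write_network(results.cerna_network, out / "cerna_network.graphml", "GraphML")
    write_network(results.cerna_network, out / "cerna_network.sif", "SIF")
    if results.enrichment:
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id, "term_name": r.term_name,
                    "namespace": r.namespace.value, "k": r.k_overlap, "n": r.n_query,
                    "K": r.K_term, "N": r.N_universe,
                    "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                }
                for r in results.enrichment
            ]
        ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if results.qpcr:
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "case_mean_fold": r.case_mean_fold, "case_sd_fold": r.case_sd_fold,
                    "control_mean_fold": r.control_mean_fold,
                    "control_sd_fold": r.control_sd_fold,
                    "t": r.t_statistic, "p_value": r.p_value,
                }
                for r in results.qpcr
            ]
        ).to_csv(out / "qpcr_summary.tsv", sep="\t", index=False)

    summary = dict(results.counts_log)
    if sim_info is not None:
        sim_info["truth"].to_json(out / "ground_truth.json")
        summary["recovery"] = _recovery_report(results, sim_info["truth"])
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "summary.txt").write_text(results.summary() + "\n")
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config_data.get("seed", config_data.get("simulate", {}).get("seed")
                                 if isinstance(config_data.get("simulate"), dict) else None),
        "spongenet_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
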