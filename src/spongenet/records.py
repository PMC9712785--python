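"""Core domain records shared by every stage of the sponge-network pipeline.

The pipeline manipulates four kinds of evidence: per-feature differential
expression (:class:`DeRecord`), pairwise sponge/targeting interactions
(:class:`InteractionEdge`), gene-set annotations (:class:`AnnotationSet`)
and qPCR cycle thresholds (:class:`CtTable`).  All of them are lightweight
frozen dataclasses validated at construction time, so downstream code can
assume the invariants hold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import pandas as pd

__all__ = [
    "RnaClass",
    "Direction",
    "DeRecord",
    "InteractionEdge",
    "AnnotationSet",
    "CtTable",
    "SeedSite",
    "CeRNATriad",
    "FormatError",
    "ValidationError",
]


class FormatError(ValueError):
    """An input file does not have the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. sign/regulation conflict)."""


class RnaClass(str, enum.Enum):
    CIRC = "circRNA"
    MIRNA = "miRNA"
    MRNA = "mRNA"

    @classmethod
    def parse(cls, value: "RnaClass | str") -> "RnaClass":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower().replace("-", "").replace("_", "")
        aliases = {
            "circrna": cls.CIRC,
            "circ": cls.CIRC,
            "mirna": cls.MIRNA,
            "mir": cls.MIRNA,
            "mrna": cls.MRNA,
            "gene": cls.MRNA,
        }
        try:
            return aliases[text]
        except KeyError:
            raise ValidationError(f"unknown RNA class: {value!r}") from None


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"

    @classmethod
    def parse(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        text = str(value).strip().lower()
        if text in ("up", "upregulated", "+"):
            return cls.UP
        if text in ("down", "downregulated", "-"):
            return cls.DOWN
        raise ValidationError(f"unknown regulation direction: {value!r}")

    @property
    def opposite(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP


@dataclass(frozen=True)
class DeRecord:
    """One feature's differential-expression evidence (case vs control).

    ``direction`` is redundant with ``sign(log2fc)`` and is checked against
    it; a zero log2 fold change is rejected as directionless.
    """

    feature_id: str
    rna_class: RnaClass
    log2fc: float
    p_value: float
    direction: Direction | None = None
    extras: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rna_class", RnaClass.parse(self.rna_class))
        if not math.isfinite(self.log2fc):
            raise ValidationError(f"{self.feature_id}: log2fc must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"{self.feature_id}: p-value {self.p_value} outside (0, 1]"
            )
        derived = Direction.UP if self.log2fc > 0 else Direction.DOWN
        if self.log2fc == 0.0:
            raise ValidationError(
                f"{self.feature_id}: log2fc == 0 has no regulation direction"
            )
        if self.direction is None:
            object.__setattr__(self, "direction", derived)
        else:
            object.__setattr__(self, "direction", Direction.parse(self.direction))
            if self.direction is not derived:
                raise ValidationError(
                    f"{self.feature_id}: regulation {self.direction.value!r} "
                    f"conflicts with sign of log2fc {self.log2fc}"
                )

    def __hash__(self) -> int:
        # extras is a plain mapping, so hash on the identifying fields only
        # (records equal under __eq__ always agree on these)
        return hash((self.feature_id, self.rna_class, self.log2fc, self.p_value))


_VALID_EDGE_CLASSES = {
    (RnaClass.CIRC, RnaClass.MIRNA),
    (RnaClass.MIRNA, RnaClass.MRNA),
}


@dataclass(frozen=True)
class InteractionEdge:
    """A predicted sponge (circRNA-miRNA) or targeting (miRNA-mRNA) interaction."""

    source_id: str
    source_class: RnaClass
    target_id: str
    target_class: RnaClass
    sources: frozenset[str] = frozenset()
    score: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_class", RnaClass.parse(self.source_class))
        object.__setattr__(self, "target_class", RnaClass.parse(self.target_class))
        object.__setattr__(self, "sources", frozenset(self.sources))
        if (self.source_class, self.target_class) not in _VALID_EDGE_CLASSES:
            raise ValidationError(
                f"invalid edge classes ({self.source_class.value}, "
                f"{self.target_class.value}) for {self.source_id}->{self.target_id}"
            )
        if self.source_id == self.target_id:
            raise ValidationError(f"self-loop on {self.source_id}")
        if not self.sources:
            raise ValidationError(
                f"{self.source_id}->{self.target_id}: evidence label set is empty"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source_id, self.target_id)


def dedupe_edges(edges: Iterable[InteractionEdge]) -> list[InteractionEdge]:
    """Merge duplicate (source, target) pairs, unioning evidence labels.

    The best (max) score among duplicates is retained; first-seen order of
    pairs is preserved.
    """
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for edge in edges:
        prev = merged.get(edge.pair)
        if prev is None:
            merged[edge.pair] = edge
        else:
            scores = [s for s in (prev.score, edge.score) if s is not None]
            merged[edge.pair] = InteractionEdge(
                source_id=edge.source_id,
                source_class=edge.source_class,
                target_id=edge.target_id,
                target_class=edge.target_class,
                sources=prev.sources | edge.sources,
                score=max(scores) if scores else None,
            )
    return list(merged.values())


class Namespace(str, enum.Enum):
    BP = "BP"
    MF = "MF"
    CC = "CC"
    PATHWAY = "pathway"


@dataclass(frozen=True)
class AnnotationSet:
    """One GO term or pathway with its member gene ids."""

    term_id: str
    term_name: str
    namespace: Namespace
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"{self.term_id}: empty member set")


class CtTable:
    """qPCR cycle thresholds by sample, gene and reference gene.

    Wraps a DataFrame with columns ``sample_id, group, gene_id, ct,
    reference_gene``; the constructor enforces that every measured
    (sample, gene) has a matching reference-gene measurement in the same
    sample.
    """

    COLUMNS = ("sample_id", "group", "gene_id", "ct", "reference_gene")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"CtTable missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        frame["ct"] = frame["ct"].astype(float)
        bad_group = set(frame["group"]) - {"case", "control"}
        if bad_group:
            raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
        if not frame["ct"].map(math.isfinite).all() or (frame["ct"] <= 0).any():
            raise ValidationError("CT values must be finite and positive")
        measured = set(zip(frame["sample_id"], frame["gene_id"]))
        for _, row in frame.iterrows():
            ref = row["reference_gene"]
            if row["gene_id"] == ref:
                continue
            if (row["sample_id"], ref) not in measured:
                raise ValidationError(
                    f"sample {row['sample_id']!r} lacks a measurement of its "
                    f"reference gene {ref!r} for gene {row['gene_id']!r}"
                )
        self.frame = frame.reset_index(drop=True)

    def genes(self) -> list[str]:
        refs = set(self.frame["reference_gene"])
        return [g for g in dict.fromkeys(self.frame["gene_id"]) if g not in refs]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CtTable) and self.frame.equals(other.frame)


class SiteType(str, enum.Enum):
    """Canonical miRNA seed-site classes, strongest to weakest."""

    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer_m8"
    SEVENMER_A1 = "7mer_A1"
    SIXMER = "6mer"


@dataclass(frozen=True)
class SeedSite:
    """One seed match of a miRNA on a target, 0-based half-open coordinates."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    site_type: SiteType
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"bad site interval [{self.start}, {self.end}) on {self.target_id}"
            )


@dataclass(frozen=True)
class CeRNATriad:
    """A circRNA-miRNA-mRNA triple with direction-consistency flags."""

    circ_id: str
    circ_direction: Direction | None
    mirna_id: str
    mirna_direction: Direction | None
    mrna_id: str
    mrna_direction: Direction | None
    circ_mirna_opposite: bool = field(init=False)
    mirna_mrna_opposite: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "circ_mirna_opposite",
            _opposite(self.circ_direction, self.mirna_direction),
        )
        object.__setattr__(
            self,
            "mirna_mrna_opposite",
            _opposite(self.mirna_direction, self.mrna_direction),
        )


def _opposite(a: Direction | None, b: Direction | None) -> bool:
    return a is not None and b is not None and a is b.opposite
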