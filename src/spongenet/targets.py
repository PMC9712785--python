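"""miRNA seed-match site finding and two-source interaction prediction.

Canonical seed sites are defined on the target (5'->3') as Watson-Crick
reverse complements of the miRNA seed:

* 6mer      — complement of miRNA positions 2-7;
* 7mer-m8   — 6mer plus pairing at miRNA position 8 (one nt 5' of the core
  on the target);
* 7mer-A1   — 6mer plus an ``A`` in the target opposite miRNA position 1
  (one nt 3' of the core);
* 8mer      — both of the above.

Two deterministic predictor variants act as independent evidence sources:
one calls an interaction when at least ``min_sites`` seed sites are found,
the other when the best duplex score reaches ``min_score``.  Their calls
are combined per pair by union or intersection — intersection for
miRNA-mRNA targeting (consensus of two sources), union for circRNA
sponging by default.

circRNA targets are circular molecules: with ``circular=True`` the scan
also covers the window spanning the back-splice junction (the last 7 nt
joined to the first 7 nt); junction-spanning sites keep coordinates on the
linearized sequence, so their end may exceed the sequence length (wrap).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .records import InteractionEdge, RnaClass, SeedSite, SiteType, ValidationError

__all__ = [
    "find_seed_sites",
    "score_duplex",
    "predict_interactions",
    "SITE_WEIGHTS",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SITE_WEIGHTS = {
    SiteType.EIGHTMER: 4.0,
    SiteType.SEVENMER_M8: 3.0,
    SiteType.SEVENMER_A1: 2.0,
    SiteType.SIXMER: 1.0,
}

_JUNCTION_WINDOW = 7  # nt kept on each side of the back-splice junction


def _normalize(seq: str, label: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(f"{label}: ambiguity codes not supported: {sorted(bad)}")
    return seq


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def find_seed_sites(
    mirna_seq: str,
    target_seq: str,
    mirna_id: str = "",
    target_id: str = "",
    circular: bool = False,
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one target sequence.

    Overlapping sites are all reported (one per 6mer-core position, with its
    strongest classification).  U and T are treated equivalently.
    """
    mir = _normalize(mirna_seq, mirna_id or "miRNA")
    if len(mir) < 8:
        raise ValidationError(f"{mirna_id or 'miRNA'}: length must be >= 8")
    length = len(target_seq)
    target = _normalize(target_seq, target_id or "target")
    if circular and length > _JUNCTION_WINDOW:
        target = target + target[:_JUNCTION_WINDOW]

    core = _revcomp(mir[1:7])  # complement of seed positions 2-7
    m8_partner = _COMPLEMENT[mir[7]]  # target nt opposite miRNA position 8
    sites: list[SeedSite] = []
    start = target.find(core)
    while start != -1:
        if start >= length:  # wrapped copy of a site already seen at start - length
            break
        has_m8 = start >= 1 and target[start - 1] == m8_partner
        has_a1 = start + 6 < len(target) and target[start + 6] == "A"
        if has_m8 and has_a1:
            site_type, lo, hi = SiteType.EIGHTMER, start - 1, start + 7
        elif has_m8:
            site_type, lo, hi = SiteType.SEVENMER_M8, start - 1, start + 6
        elif has_a1:
            site_type, lo, hi = SiteType.SEVENMER_A1, start, start + 7
        else:
            site_type, lo, hi = SiteType.SIXMER, start, start + 6
        sites.append(
            SeedSite(
                mirna_id=mirna_id,
                target_id=target_id,
                start=lo,
                end=hi,
                site_type=site_type,
                score=SITE_WEIGHTS[site_type],
            )
        )
        start = target.find(core, start + 1)
    return sites


def _core_start(site: SeedSite) -> int:
    # coordinate of the 6mer core (complement of seed 2-7) on the target
    if site.site_type in (SiteType.EIGHTMER, SiteType.SEVENMER_M8):
        return site.start + 1
    return site.start


def score_duplex(
    site: SeedSite, mirna_seq: str, target_seq: str, flank: int = 4
) -> float:
    """Seed-type weight plus a 3'-supplementary pairing bonus.

    The bonus counts Watson-Crick pairs between miRNA positions 13..12+flank
    and the target nucleotides aligned antiparallel to them (miRNA position
    ``i`` faces target coordinate ``core_start + 7 - i``).  Deterministic.
    """
    mir = _normalize(mirna_seq, site.mirna_id or "miRNA")
    target = _normalize(target_seq, site.target_id or "target")
    s = _core_start(site)
    bonus = 0
    for pos in range(13, 13 + flank):  # 1-based miRNA positions
        if pos > len(mir):
            break
        t_coord = s + 7 - pos
        if 0 <= t_coord < len(target) and target[t_coord] == _COMPLEMENT[mir[pos - 1]]:
            bonus += 1
    return SITE_WEIGHTS[site.site_type] + bonus


def _as_mapping(fasta: "Mapping[str, str] | str | Path") -> Mapping[str, str]:
    if isinstance(fasta, (str, Path)):
        from .io import read_fasta

        return read_fasta(fasta)
    return fasta


def predict_interactions(
    mirna_fasta: "Mapping[str, str] | str | Path",
    target_fasta: "Mapping[str, str] | str | Path",
    target_class: RnaClass | str,
    policy: str = "union",
    min_score: float = 2.0,
    min_sites: int = 1,
    circular: bool | None = None,
    flank: int = 4,
) -> list[InteractionEdge]:
    """Predict miRNA-target interactions with a two-source consensus rule.

    Source ``seed_count`` calls a pair when it has >= ``min_sites`` seed
    sites; source ``duplex_score`` when the best duplex score is
    >= ``min_score``.  ``policy`` combines the two calls per pair.  Edges
    are emitted in sponge orientation (circRNA -> miRNA) for circRNA
    targets and targeting orientation (miRNA -> mRNA) for mRNA targets.
    """
    if policy not in ("union", "intersection"):
        raise ValueError(f"policy must be 'union' or 'intersection', got {policy!r}")
    target_class = RnaClass.parse(target_class)
    if target_class is RnaClass.MIRNA:
        raise ValidationError("targets must be circRNA or mRNA sequences")
    if circular is None:
        circular = target_class is RnaClass.CIRC
    mirnas = _as_mapping(mirna_fasta)
    targets = _as_mapping(target_fasta)
    if not mirnas or not targets:
        import warnings

        warnings.warn("empty FASTA input; no interactions predicted")
        return []

    edges: list[InteractionEdge] = []
    for mirna_id, mirna_seq in mirnas.items():
        for target_id, target_seq in targets.items():
            sites = find_seed_sites(
                mirna_seq, target_seq, mirna_id=mirna_id, target_id=target_id, circular=circular
            )
            if not sites:
                continue
            best = max(score_duplex(s, mirna_seq, target_seq, flank) for s in sites)
            calls = set()
            if len(sites) >= min_sites:
                calls.add("seed_count")
            if best >= min_score:
                calls.add("duplex_score")
            keep = bool(calls) if policy == "union" else len(calls) == 2
            if not keep:
                continue
            if target_class is RnaClass.CIRC:
                edge = InteractionEdge(
                    target_id, RnaClass.CIRC, mirna_id, RnaClass.MIRNA,
                    sources=frozenset(calls), score=best,
                )
            else:
                edge = InteractionEdge(
                    mirna_id, RnaClass.MIRNA, target_id, RnaClass.MRNA,
                    sources=frozenset(calls), score=best,
                )
            edges.append(edge)
    return edges
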