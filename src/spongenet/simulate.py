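"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a two-group (case vs control, n = 3 per group)
RNA-seq experiment over three RNA classes.  Counts are negative-binomial
(variance = mu + phi * mu^2) around log-normally jittered per-feature
baselines; a chosen subset of features is planted as differentially
expressed by scaling the case-group mean by 2^(+/- effect).  Planted ceRNA
triads are direction-consistent: the circRNA and mRNA share a direction
opposite to the miRNA's, the dominant pattern among validated sponge pairs.
Sequences carry exact 8mer seed sites at recorded coordinates for each
planted (miRNA, target) pair; chance background matches can optionally be
scrubbed so planted triads are recoverable without collisions.  qPCR cycle
thresholds are generated so that the expected 2^-ddCT equals the planted
fold change.

One integer seed governs everything.  :func:`simulate_all` draws counts,
sequences and the Ct table from a single generator stream in that order;
the stage functions can also be called independently, in which case each
derives its own stream from ``cfg.seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CtTable, Direction, RnaClass, ValidationError
from .targets import find_seed_sites, _revcomp

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_sequences",
    "simulate_ct_table",
    "simulate_all",
    "write_simulation",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror a small two-group design: three animals per group, mean
    depth-normalized baseline of 500 counts, NB dispersion 0.1 and planted
    effects of |log2FC| = 2.  Feature counts are scaled down from a whole-
    transcriptome survey to keep simulation-based tests quick while leaving
    enough null features to measure false-positive rates.
    """

    seed: int = 0
    n_per_group: int = 3
    n_circ: int = 150
    n_mirna: int = 100
    n_mrna: int = 400
    baseline_mean: float = 500.0
    dispersion: float = 0.1
    baseline_log2_sd: float = 1.0
    n_de_circ: int = 20
    n_de_mirna: int = 20
    n_de_mrna: int = 20
    effect_log2fc: float = 2.0
    n_triads: int = 10
    seed_len: int = 7
    mirna_len: int = 22
    circ_len: int = 300
    mrna_len: int = 500
    ct_noise_sd: float = 0.25
    scrub_chance_sites: bool = True

    def __post_init__(self) -> None:
        counts = {
            "n_per_group": self.n_per_group,
            "n_circ": self.n_circ,
            "n_mirna": self.n_mirna,
            "n_mrna": self.n_mrna,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValidationError(f"{name} must be positive")
        if min(self.n_de_circ, self.n_de_mirna, self.n_de_mrna) < 0:
            raise ValidationError("n_de counts must be nonnegative")
        if self.n_triads > min(self.n_de_circ, self.n_de_mirna, self.n_de_mrna):
            raise ValidationError("n_triads cannot exceed the smallest per-class n_de")
        if self.n_de_circ > self.n_circ or self.n_de_mirna > self.n_mirna or self.n_de_mrna > self.n_mrna:
            raise ValidationError("n_de cannot exceed the feature count of its class")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValidationError("baseline_mean must be > 0 and dispersion >= 0")
        if self.mirna_len < 8:
            raise ValidationError("mirna_len must be >= 8")
        site_len = 8  # planted sites are 8mers
        if min(self.circ_len, self.mrna_len) < site_len:
            raise ValidationError("target length smaller than a seed site")

    @property
    def samples(self) -> list[str]:
        return [f"case_{i + 1}" for i in range(self.n_per_group)] + [
            f"control_{i + 1}" for i in range(self.n_per_group)
        ]


@dataclass
class GroundTruth:
    """Planted signal: per-class DE effects, triads and seed-site coordinates."""

    de: dict[str, dict[str, float]]  # rna_class value -> feature_id -> signed log2FC
    triads: list[tuple[str, str, str]]
    planted_sites: list[dict] = field(default_factory=list)
    chance_sites: list[dict] = field(default_factory=list)

    def direction(self, rna_class: RnaClass, feature_id: str) -> Direction | None:
        lfc = self.de[rna_class.value].get(feature_id)
        if lfc is None:
            return None
        return Direction.UP if lfc > 0 else Direction.DOWN

    def de_ids(self, rna_class: RnaClass) -> set[str]:
        return set(self.de[rna_class.value])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de": self.de,
            "triads": [list(t) for t in self.triads],
            "planted_sites": self.planted_sites,
            "chance_sites": self.chance_sites,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de=payload["de"],
            triads=[tuple(t) for t in payload["triads"]],
            planted_sites=payload["planted_sites"],
            chance_sites=payload["chance_sites"],
        )


def _feature_ids(cfg: SimulationConfig) -> dict[RnaClass, list[str]]:
    return {
        RnaClass.CIRC: [f"circSIM{i:04d}" for i in range(cfg.n_circ)],
        RnaClass.MIRNA: [f"miR-sim-{i:03d}" for i in range(cfg.n_mirna)],
        RnaClass.MRNA: [f"GeneSim{i:04d}" for i in range(cfg.n_mrna)],
    }


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion  # NB "number of failures"; var = mu + phi mu^2
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[RnaClass, pd.DataFrame], GroundTruth]:
    """Integer count matrices (features x samples, case columns first).

    Stream order: triad direction signs, then per class (circRNA, miRNA,
    mRNA): non-triad DE signs, baseline jitter, counts.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids = _feature_ids(cfg)
    n_de = {
        RnaClass.CIRC: cfg.n_de_circ,
        RnaClass.MIRNA: cfg.n_de_mirna,
        RnaClass.MRNA: cfg.n_de_mrna,
    }
    # triad direction pattern: circ and mRNA share a sign, miRNA opposes it
    circ_signs = rng.choice([-1.0, 1.0], size=cfg.n_triads)
    triad_signs = {
        RnaClass.CIRC: circ_signs,
        RnaClass.MIRNA: -circ_signs,
        RnaClass.MRNA: circ_signs,
    }
    triads = [
        (ids[RnaClass.CIRC][i], ids[RnaClass.MIRNA][i], ids[RnaClass.MRNA][i])
        for i in range(cfg.n_triads)
    ]

    matrices: dict[RnaClass, pd.DataFrame] = {}
    de: dict[str, dict[str, float]] = {}
    n = cfg.n_per_group
    for rna_class, features in ids.items():
        k = n_de[rna_class]
        signs = np.empty(k)
        signs[: cfg.n_triads] = triad_signs[rna_class]
        if k > cfg.n_triads:
            signs[cfg.n_triads :] = rng.choice([-1.0, 1.0], size=k - cfg.n_triads)
        effects = np.zeros(len(features))
        effects[:k] = signs * cfg.effect_log2fc

        baseline = cfg.baseline_mean * 2.0 ** rng.normal(
            0.0, cfg.baseline_log2_sd, size=len(features)
        )
        case_mean = baseline * 2.0 ** effects
        mean_matrix = np.column_stack([np.tile(case_mean, (n, 1)).T.reshape(len(features), n),
                                       np.tile(baseline, (n, 1)).T.reshape(len(features), n)])
        counts = _nb_counts(rng, mean_matrix, cfg.dispersion)
        matrices[rna_class] = pd.DataFrame(counts, index=features, columns=cfg.samples)
        de[rna_class.value] = {features[i]: float(effects[i]) for i in range(k)}

    return matrices, GroundTruth(de=de, triads=triads)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _scan_all(
    mirna_seqs: dict[str, str],
    targets: dict[str, str],
    circular_ids: set[str],
) -> list[dict]:
    found = []
    # cheap substring pre-filter: a pair without the 6mer core cannot have
    # any site, and most pairs have none
    cores = {
        mid: _revcomp(mseq.upper().replace("U", "T")[1:7])
        for mid, mseq in mirna_seqs.items()
    }
    extended = {
        tid: (tseq.upper().replace("U", "T") + tseq.upper().replace("U", "T")[:7])
        if tid in circular_ids
        else tseq.upper().replace("U", "T")
        for tid, tseq in targets.items()
    }
    for mid, mseq in mirna_seqs.items():
        core = cores[mid]
        for tid, tseq in targets.items():
            if core not in extended[tid]:
                continue
            for site in find_seed_sites(mseq, tseq, mirna_id=mid, target_id=tid,
                                        circular=tid in circular_ids):
                found.append(
                    {
                        "mirna_id": mid,
                        "target_id": tid,
                        "start": site.start,
                        "end": site.end,
                        "site_type": site.site_type.value,
                    }
                )
    return found


def simulate_sequences(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Random background sequences with planted 8mer seed sites.

    Returns (miRNA sequences, target sequences for circRNAs and mRNAs);
    updates ``truth.planted_sites`` with the recorded coordinates and
    ``truth.chance_sites`` with any background match detected by an
    exhaustive scan after optional scrubbing.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ids = _feature_ids(cfg)

    # miRNAs with mutually distinct 6mer seed cores, so planted sites are
    # attributable to a single miRNA
    mirna_seqs: dict[str, str] = {}
    seen_cores: set[str] = set()
    for mid in ids[RnaClass.MIRNA]:
        while True:
            seq = _random_seq(rng, cfg.mirna_len)
            core = seq[1:7]
            if core not in seen_cores:
                seen_cores.add(core)
                mirna_seqs[mid] = seq
                break

    lengths = {RnaClass.CIRC: cfg.circ_len, RnaClass.MRNA: cfg.mrna_len}
    targets: dict[str, str] = {}
    target_class: dict[str, RnaClass] = {}
    for rna_class in (RnaClass.CIRC, RnaClass.MRNA):
        for tid in ids[rna_class]:
            targets[tid] = _random_seq(rng, lengths[rna_class])
            target_class[tid] = rna_class

    # plant one 8mer site per (miRNA, target) of every triad
    planted: list[dict] = []
    planted_regions: dict[str, list[tuple[int, int]]] = {}
    for circ_id, mirna_id, mrna_id in truth.triads:
        mseq = mirna_seqs[mirna_id]
        site_seq = _revcomp(mseq[1:8].replace("U", "T")) + "A"  # 8mer: m8..core + A1
        for tid in (circ_id, mrna_id):
            length = len(targets[tid])
            start = int(rng.integers(1, length - len(site_seq)))
            targets[tid] = targets[tid][:start] + site_seq + targets[tid][start + len(site_seq):]
            planted_regions.setdefault(tid, []).append((start, start + len(site_seq)))
            planted.append(
                {
                    "mirna_id": mirna_id,
                    "target_id": tid,
                    "start": start,
                    "end": start + len(site_seq),
                    "site_type": "8mer",
                }
            )
    truth.planted_sites = planted

    circular_ids = set(ids[RnaClass.CIRC])
    planted_keys = {
        (p["mirna_id"], p["target_id"], p["start"], p["end"]) for p in planted
    }
    planted_pairs = {(p["mirna_id"], p["target_id"]) for p in planted}

    def classify(found: list[dict]) -> list[dict]:
        chance = []
        for site in found:
            key = (site["mirna_id"], site["target_id"], site["start"], site["end"])
            pair = (site["mirna_id"], site["target_id"])
            # sub-sites nested inside a planted 8mer of the same pair are
            # that site, not collisions
            if key in planted_keys:
                continue
            if pair in planted_pairs and any(
                lo <= site["start"] and site["end"] <= hi
                for lo, hi in planted_regions.get(site["target_id"], ())
            ):
                continue
            chance.append(site)
        return chance

    if cfg.scrub_chance_sites:
        for _ in range(25):
            chance = classify(_scan_all(mirna_seqs, targets, circular_ids))
            fixable = False
            for site in chance:
                tid = site["target_id"]
                seq = targets[tid]
                protected = planted_regions.get(tid, [])
                positions = [
                    p % len(seq)
                    for p in range(site["start"], site["end"])
                    if not any(lo <= p % len(seq) < hi for lo, hi in protected)
                ]
                if not positions:
                    continue  # unfixable overlap with a planted region
                pos = positions[len(positions) // 2]
                current = seq[pos]
                replacement = str(rng.choice([b for b in "ACGT" if b != current]))
                targets[tid] = seq[:pos] + replacement + seq[pos + 1:]
                fixable = True
            if not chance or not fixable:
                break

    truth.chance_sites = classify(_scan_all(mirna_seqs, targets, circular_ids))
    return mirna_seqs, targets


def simulate_ct_table(
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    base_dct: float = 5.0,
) -> CtTable:
    """Cycle thresholds whose expected 2^-ddCT equals the planted fold change.

    Reference-gene CTs are Normal(20, 0.2) per sample (GAPDH for circRNA and
    mRNA, U6 for miRNA); each target gene's CT is the sample's reference CT
    plus a constant offset, shifted by -log2FC in case samples, plus
    Gaussian noise of sd ``cfg.ct_noise_sd``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    samples = cfg.samples
    references = {"GAPDH": None, "U6": None}
    ref_ct = {
        ref: {s: 20.0 + rng.normal(0.0, 0.2) for s in samples} for ref in references
    }
    rows = []
    for ref in references:
        for s in samples:
            rows.append(
                {
                    "sample_id": s,
                    "group": "case" if s.startswith("case") else "control",
                    "gene_id": ref,
                    "ct": ref_ct[ref][s],
                    "reference_gene": ref,
                }
            )
    genes: list[tuple[str, RnaClass]] = []
    for circ_id, mirna_id, mrna_id in truth.triads:
        genes.extend(
            [(circ_id, RnaClass.CIRC), (mirna_id, RnaClass.MIRNA), (mrna_id, RnaClass.MRNA)]
        )
    for gene, rna_class in genes:
        lfc = truth.de[rna_class.value][gene]
        ref = "U6" if rna_class is RnaClass.MIRNA else "GAPDH"
        for s in samples:
            is_case = s.startswith("case")
            ct = ref_ct[ref][s] + base_dct - (lfc if is_case else 0.0)
            if cfg.ct_noise_sd > 0:
                ct += rng.normal(0.0, cfg.ct_noise_sd)
            rows.append(
                {
                    "sample_id": s,
                    "group": "case" if is_case else "control",
                    "gene_id": gene,
                    "ct": ct,
                    "reference_gene": ref,
                }
            )
    return CtTable(pd.DataFrame(rows))


def simulate_all(cfg: SimulationConfig):
    """Counts, sequences and Ct table from one generator stream.

    Returns ``(matrices, mirna_seqs, target_seqs, ct_table, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    matrices, truth = simulate_counts(cfg, rng)
    mirna_seqs, target_seqs = simulate_sequences(cfg, truth, rng)
    ct = simulate_ct_table(cfg, truth, rng)
    return matrices, mirna_seqs, target_seqs, ct, truth


def write_simulation(cfg: SimulationConfig, out_dir: str | Path) -> Path:
    """Run :func:`simulate_all` and write every artifact under ``out_dir``."""
    from .io import write_ct_table, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, mirna_seqs, target_seqs, ct, truth = simulate_all(cfg)
    for rna_class, matrix in matrices.items():
        matrix.to_csv(out / f"counts_{rna_class.value}.tsv", sep="\t", index_label="feature_id")
    write_fasta(mirna_seqs, out / "mirna.fa")
    write_fasta(target_seqs, out / "targets.fa")
    write_ct_table(ct, out / "ct_table.tsv")
    truth.to_json(out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=1, sort_keys=True))
    return out
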