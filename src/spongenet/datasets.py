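"""Packaged reference tables from the 5xFAD hippocampus circRNA study.

Three small fixtures ship with the package:

* ``circrna_de.tsv``  — the 34 differentially expressed circRNAs (log2FC,
  p-value, regulation, GC%, structural type);
* ``mirna_de.tsv``    — the 12 differentially expressed miRNAs;
* ``hub_interactions.tsv`` — the six validated hub circRNA-miRNA sponge
  interactions.

These are the printed study tables, used as ground truth for the screening
arithmetic and the hub sponge graph.
"""

from __future__ import annotations

from importlib import resources

from .records import DeRecord, InteractionEdge, RnaClass

__all__ = ["load_circrna_de", "load_mirna_de", "load_hub_interactions", "fixture_path"]


def fixture_path(name: str):
    """Filesystem path of a packaged fixture (context-manager free in practice:
    the package is installed from source, so files live on disk)."""
    return resources.files("spongenet.data").joinpath(name)


def load_circrna_de() -> list[DeRecord]:
    """The 34 differentially expressed circRNAs (17 up, 17 down)."""
    from .io import read_de_table

    return read_de_table(fixture_path("circrna_de.tsv"), RnaClass.CIRC)


def load_mirna_de() -> list[DeRecord]:
    """The 12 differentially expressed miRNAs (9 up, 3 down)."""
    from .io import read_de_table

    return read_de_table(fixture_path("mirna_de.tsv"), RnaClass.MIRNA)


def load_hub_interactions() -> list[InteractionEdge]:
    """The six hub circRNA-miRNA sponge interactions (5 circRNAs, 4 miRNAs)."""
    from .io import read_edge_list

    return read_edge_list(
        fixture_path("hub_interactions.tsv"), RnaClass.CIRC, RnaClass.MIRNA
    )
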