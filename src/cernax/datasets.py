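"""Packaged literature-curated gallbladder-cancer (GBC) axis fixtures.

Two small catalogs transcribed from published GBC ceRNA work are
shipped with the package so the triad-assembly machinery can be
exercised without any external input:

``gbc_hub_axes``
    sponge axes around the three PPI hub genes on the p53 signalling
    pathway (TP53, CCND1, CTNNB1), including the three functionally
    validated TP53 regulators miR-125b-5p, miR-34a-5p and miR-30a-5p.
``gbc_dual_axes``
    the six sponge axes around the targets differentially expressed at
    both the mRNA and the protein level, EZH2 and PTMA
    (TUG1/MALAT1–miR-26a-5p–EZH2, NEAT1/MALAT1–miR-101-3p–EZH2,
    TUG1/MALAT1–miR-1-3p–PTMA).

The interaction partners and evidence tiers are curated; the direction
calls in the fixtures are synthetic sponge-consistent assignments
(tumour genes up, their miRNAs down, sponges up), since the pipeline
consumes directions rather than expression magnitudes.
"""

from __future__ import annotations

from importlib import resources

from . import catalog_io
from .cerna import DirectionCalls
from .models import LncMirEdge, MirTargetEdge, MoleculeClass


def _load(name: str) -> tuple[list[MirTargetEdge], list[LncMirEdge], DirectionCalls]:
    root = resources.files(__package__) / "data" / name
    with resources.as_file(root) as path:
        mir_catalog = catalog_io.read_mir_target_table(path / "mir_targets.tsv")
        lnc_catalog = catalog_io.read_lnc_mir_table(path / "lnc_mir.tsv")
        tables = catalog_io.read_direction_table(path / "calls.tsv")
    calls = DirectionCalls(
        mirna=tables.get(MoleculeClass.MIRNA, {}),
        target=tables.get(MoleculeClass.MRNA, {}),
        lncrna=tables.get(MoleculeClass.LNCRNA, {}),
    )
    return mir_catalog, lnc_catalog, calls


def load_gbc_hub_axes() -> tuple[list[MirTargetEdge], list[LncMirEdge], DirectionCalls]:
    """Sponge-axis catalog around TP53, CCND1 and CTNNB1."""
    return _load("gbc_hub_axes")


def load_gbc_dual_axes() -> tuple[list[MirTargetEdge], list[LncMirEdge], DirectionCalls]:
    """Sponge-axis catalog around the dual-level targets EZH2 and PTMA."""
    return _load("gbc_dual_axes")
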