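"""Inverse-expression pairing, confidence filtering and layer integration.

The retained miRNA-target catalog is the intersection of three pure
filters applied to a candidate-edge catalog:

* both endpoints carry a usable direction call;
* the two directions are opposite (miRNA-up/target-down or the reverse);
* the interaction is experimentally observed, or predicted with a
  TargetScan cumulative weighted context score (CWCS) of at most −0.4.

Two layers are built independently — target directions from the mRNA
consensus for the transcript layer and from the protein consensus for
the protein layer — and integrated into a non-redundant catalog keyed by
(miRNA, target). Targets called in both classes are flagged dual-level,
and dual-concordant when the two calls agree in sign.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

from .models import Confidence, Direction, MirTargetEdge, PairedInteraction

logger = logging.getLogger(__name__)

#: CWCS retention cutoff: predicted edges are kept at −0.4 or lower.
DEFAULT_CWCS_CUTOFF = -0.4


def confidence_filter(
    edges: Iterable[MirTargetEdge], cwcs_cutoff: float = DEFAULT_CWCS_CUTOFF
) -> list[MirTargetEdge]:
    """Keep observed edges, and predicted edges with CWCS ≤ cutoff
    (boundary inclusive)."""
    kept = [
        e
        for e in edges
        if e.confidence is Confidence.OBSERVED
        or (e.cwcs is not None and e.cwcs <= cwcs_cutoff)
    ]
    return kept


def expression_pair(
    edges: Iterable[MirTargetEdge],
    mirna_calls: Mapping[str, Direction],
    target_calls: Mapping[str, Direction],
) -> list[PairedInteraction]:
    """Retain edges whose miRNA and target have opposite direction calls.

    Edges referencing a molecule without a usable call are dropped (the
    drop count is logged); retained edges are annotated with both
    directions.
    """
    retained: list[PairedInteraction] = []
    n_unmapped = 0
    for edge in edges:
        mir_dir = mirna_calls.get(edge.mirna_id)
        tgt_dir = target_calls.get(edge.target_symbol)
        if mir_dir is None or tgt_dir is None:
            n_unmapped += 1
            continue
        if mir_dir != tgt_dir:
            retained.append(PairedInteraction(edge, mir_dir, tgt_dir))
    if n_unmapped:
        logger.info("expression_pair: dropped %d edge(s) without direction calls", n_unmapped)
    return retained


def integrate_layers(
    transcript_set: Sequence[PairedInteraction],
    protein_set: Sequence[PairedInteraction],
    mrna_calls: Optional[Mapping[str, Direction]] = None,
    protein_calls: Optional[Mapping[str, Direction]] = None,
) -> list[PairedInteraction]:
    """Union the transcript- and protein-derived paired sets into one
    non-redundant catalog keyed by (miRNA, target).

    A merged edge carries the union of layers and evidence methods, and
    is observed if either source says observed. ``dual_level`` marks
    targets with usable calls in both the mRNA and the protein class;
    ``dual_concordant`` additionally requires those calls to agree.
    An edge whose two layers disagree on the target direction is kept
    but flagged discordant and never dual-concordant.
    """
    mrna_calls = mrna_calls or {}
    protein_calls = protein_calls or {}

    merged: dict[tuple, PairedInteraction] = {}
    n_discordant = 0
    for pair in list(transcript_set) + list(protein_set):
        key = pair.edge.key()
        if key not in merged:
            merged[key] = pair
            continue
        prev = merged[key]
        edge = _merge_edges(prev.edge, pair.edge)
        discordant = (
            prev.discordant_layers
            or pair.discordant_layers
            or prev.target_direction != pair.target_direction
        )
        if prev.target_direction != pair.target_direction:
            n_discordant += 1
        merged[key] = PairedInteraction(
            edge,
            prev.mirna_direction,
            prev.target_direction,
            discordant_layers=discordant,
        )
    if n_discordant:
        logger.warning(
            "integrate_layers: %d edge(s) have discordant target directions between layers",
            n_discordant,
        )

    out: list[PairedInteraction] = []
    for pair in merged.values():
        target = pair.edge.target_symbol
        m_dir, p_dir = mrna_calls.get(target), protein_calls.get(target)
        dual = m_dir is not None and p_dir is not None
        concordant = dual and m_dir == p_dir and not pair.discordant_layers
        out.append(
            PairedInteraction(
                pair.edge,
                pair.mirna_direction,
                pair.target_direction,
                dual_level=dual,
                dual_concordant=concordant,
                discordant_layers=pair.discordant_layers,
            )
        )
    return out


def _merge_edges(a: MirTargetEdge, b: MirTargetEdge) -> MirTargetEdge:
    confidence = (
        Confidence.OBSERVED
        if Confidence.OBSERVED in (a.confidence, b.confidence)
        else Confidence.PREDICTED
    )
    cwcs = a.cwcs if a.cwcs is not None else b.cwcs
    if a.cwcs is not None and b.cwcs is not None:
        cwcs = min(a.cwcs, b.cwcs)
    return MirTargetEdge(
        a.mirna_id,
        a.target_symbol,
        confidence,
        cwcs,
        a.layers | b.layers,
        a.evidence_methods | b.evidence_methods,
    )


def observed_subset(
    catalog: Iterable[PairedInteraction],
) -> tuple[list[PairedInteraction], int]:
    """Return the experimentally observed interactions and the number of
    distinct targets among them."""
    observed = [p for p in catalog if p.edge.confidence is Confidence.OBSERVED]
    n_targets = len({p.edge.target_symbol for p in observed})
    return observed, n_targets
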