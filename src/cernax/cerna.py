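"""Sponge-consistent lncRNA – miRNA – mRNA triad assembly.

For each anchor gene, the retained (inverse-paired, confidence-filtered)
miRNA partners are joined to the lncRNA–miRNA catalog. Because sponge
databases index mature arms while differential-expression lists often do
not, a miRNA id without a ``-3p``/``-5p`` suffix is expanded to both
arms for the lncRNA join only; the triad records the arm-resolved id and
whether it arose from expansion.

A triad is consistent with the ceRNA model when the lncRNA (the sponge)
and the mRNA (the protected target) share a direction and the miRNA
opposes it — sequestering the miRNA de-represses the target, so sponge
and target are positively co-expressed. Only consistent triads are
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from . import pairing
from .models import (
    CeRNATriad,
    Direction,
    EvidenceTier,
    LncMirEdge,
    MirTargetEdge,
    STRONG_EVIDENCE_METHODS,
)

logger = logging.getLogger(__name__)


def expand_arms(mirna_id: str) -> set[str]:
    """Arm-resolve a miRNA id: ids already ending in -3p/-5p are kept as
    is; otherwise both mature arms are generated."""
    if mirna_id.endswith("-3p") or mirna_id.endswith("-5p"):
        return {mirna_id}
    return {mirna_id + "-3p", mirna_id + "-5p"}


def strip_arm(mirna_id: str) -> str:
    if mirna_id.endswith("-3p") or mirna_id.endswith("-5p"):
        return mirna_id[:-3]
    return mirna_id


def tier_mir_target(edge: MirTargetEdge) -> EvidenceTier:
    """Strong iff any functional-validation assay (reporter assay,
    western blot, qPCR) backs the edge; high-throughput-only support is
    less strong."""
    if edge.evidence_methods & STRONG_EVIDENCE_METHODS:
        return EvidenceTier.STRONG
    return EvidenceTier.LESS_STRONG


@dataclass(frozen=True)
class DirectionCalls:
    """Usable (non-ambiguous) direction calls per molecular layer."""

    mirna: Mapping[str, Direction] = field(default_factory=dict)
    target: Mapping[str, Direction] = field(default_factory=dict)
    lncrna: Mapping[str, Direction] = field(default_factory=dict)

    def mirna_direction(self, mirna_id: str) -> Optional[Direction]:
        """Look up a miRNA call, trying the arm-resolved id first and
        falling back to the arm-less base id (expression studies mix
        both conventions)."""
        if mirna_id in self.mirna:
            return self.mirna[mirna_id]
        return self.mirna.get(strip_arm(mirna_id))


def assemble_triads(
    anchors: Iterable[str],
    mir_catalog: Sequence[MirTargetEdge],
    lnc_catalog: Sequence[LncMirEdge],
    calls: DirectionCalls,
    cwcs_cutoff: float = pairing.DEFAULT_CWCS_CUTOFF,
) -> tuple[list[CeRNATriad], list[str]]:
    """Assemble consistent triads for the anchor genes.

    Returns ``(triads, anchors_without_triads)``; the second list makes
    anchors that found no sponge explicit. Raises ``ValueError`` for an
    anchor without a direction call.
    """
    anchors = sorted(set(anchors))
    for anchor in anchors:
        if anchor not in calls.target:
            raise ValueError(f"anchor {anchor!r} has no direction call")

    lnc_by_mirna: dict[str, list[LncMirEdge]] = {}
    for e in lnc_catalog:
        lnc_by_mirna.setdefault(e.mirna_id, []).append(e)

    retained = pairing.confidence_filter(mir_catalog, cwcs_cutoff)
    triads: list[CeRNATriad] = []
    empty_anchors: list[str] = []
    for anchor in anchors:
        target_dir = calls.target[anchor]
        found = False
        for edge in retained:
            if edge.target_symbol != anchor:
                continue
            mir_dir = calls.mirna_direction(edge.mirna_id)
            if mir_dir is None or mir_dir == target_dir:
                continue  # inverse pairing is definitional
            for arm_id in sorted(expand_arms(edge.mirna_id)):
                expanded = arm_id != edge.mirna_id
                for lnc_edge in lnc_by_mirna.get(arm_id, []):
                    lnc_dir = calls.lncrna.get(lnc_edge.lncrna_id)
                    if lnc_dir is None:
                        continue
                    triad = CeRNATriad(
                        lncrna_id=lnc_edge.lncrna_id,
                        mirna_id=arm_id,
                        target_symbol=anchor,
                        lnc_direction=lnc_dir,
                        mir_direction=mir_dir,
                        target_direction=target_dir,
                        mir_target_tier=tier_mir_target(edge),
                        lnc_mir_tier=lnc_edge.tier,
                        arm_expanded=expanded,
                    )
                    if triad.consistent:
                        triads.append(triad)
                        found = True
        if not found:
            empty_anchors.append(anchor)
    if empty_anchors:
        logger.info("no sponge triad found for anchor(s): %s", ", ".join(empty_anchors))
    return triads, empty_anchors


def triads_to_network(triads: Sequence[CeRNATriad]) -> nx.Graph:
    """Tri-partite attributed network: node attributes ``node_class``
    (lncRNA/miRNA/mRNA) and ``direction`` (up/down), edge attributes
    ``relation`` (sponges/targets) and ``evidence_tier``."""
    g = nx.Graph()
    for t in triads:
        g.add_node(t.lncrna_id, node_class="lncRNA", direction=t.lnc_direction.value)
        g.add_node(t.mirna_id, node_class="miRNA", direction=t.mir_direction.value)
        g.add_node(t.target_symbol, node_class="mRNA", direction=t.target_direction.value)
        g.add_edge(
            t.lncrna_id, t.mirna_id, relation="sponges", evidence_tier=t.lnc_mir_tier.value
        )
        g.add_edge(
            t.mirna_id,
            t.target_symbol,
            relation="targets",
            evidence_tier=t.mir_target_tier.value,
        )
    return g


def export_cerna_network(triads: Sequence[CeRNATriad], path, fmt: str = "graphml") -> nx.Graph:
    """Write the triad network (SIF / GraphML / TSV); returns the graph."""
    from . import catalog_io

    if not triads:
        raise ValueError("export_cerna_network requires at least one triad")
    g = triads_to_network(triads)
    catalog_io.write_network(g, path, fmt)
    return g
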