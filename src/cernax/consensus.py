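"""Majority-rule direction consensus across studies (and transcripts).

A molecule is called up (down) when strictly more than half of its
voting units report that trend; an exact split is ambiguous and the
molecule is flagged excluded from all further analysis. When the
evidence is transcript-resolved the rule is applied twice: one vote per
transcript by strict majority of that transcript's studies, then strict
majority over the transcript votes. Ambiguous transcripts abstain at
the outer level (they do not enter the denominator), keeping the
">50% of the transcripts" rule well-defined.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping

from .models import (
    ConsensusCall,
    ConsensusDirection,
    Direction,
    ExpressionEvidence,
    MoleculeClass,
)

logger = logging.getLogger(__name__)


def _majority(n_up: int, n_down: int) -> ConsensusDirection:
    total = n_up + n_down
    if n_up * 2 > total:
        return ConsensusDirection.UP
    if n_down * 2 > total:
        return ConsensusDirection.DOWN
    return ConsensusDirection.AMBIGUOUS


def call_consensus(evidence: Iterable[ExpressionEvidence]) -> ConsensusCall:
    """Collapse one molecule's evidence into a single direction call.

    Raises ``ValueError`` if the evidence list is empty or mixes
    molecules/classes.
    """
    evidence = list(evidence)
    if not evidence:
        raise ValueError("call_consensus requires at least one evidence record")
    keys = {(e.molecule_id, e.molecule_class) for e in evidence}
    if len(keys) > 1:
        raise ValueError(f"evidence mixes molecules/classes: {sorted(keys)}")
    molecule_id, molecule_class = next(iter(keys))

    if any(e.transcript_id is not None for e in evidence):
        by_transcript: dict = defaultdict(list)
        for e in evidence:
            by_transcript[e.transcript_id].append(e.direction)
        n_up = n_down = 0
        for directions in by_transcript.values():
            vote = _majority(
                sum(d is Direction.UP for d in directions),
                sum(d is Direction.DOWN for d in directions),
            )
            if vote is ConsensusDirection.UP:
                n_up += 1
            elif vote is ConsensusDirection.DOWN:
                n_down += 1
            # ambiguous transcripts abstain
    else:
        n_up = sum(e.direction is Direction.UP for e in evidence)
        n_down = sum(e.direction is Direction.DOWN for e in evidence)

    return ConsensusCall(molecule_id, molecule_class, _majority(n_up, n_down), n_up, n_down)


def consensus_table(
    evidence: Iterable[ExpressionEvidence],
) -> dict[MoleculeClass, dict[str, ConsensusCall]]:
    """Build the per-class consensus table for a full evidence catalog.

    Ambiguous molecules are retained in the table (flagged by their
    direction) but are excluded from everything downstream; the
    exclusion count is logged. A molecule measured in several classes
    (e.g. as mRNA and as protein) is called independently per class.
    """
    groups: dict = defaultdict(list)
    for e in evidence:
        groups[(e.molecule_class, e.molecule_id)].append(e)

    table: dict[MoleculeClass, dict[str, ConsensusCall]] = defaultdict(dict)
    n_excluded = 0
    for (molecule_class, molecule_id), records in groups.items():
        call = call_consensus(records)
        table[molecule_class][molecule_id] = call
        if not call.usable:
            n_excluded += 1
    if not groups:
        logger.warning("consensus_table received an empty catalog")
    if n_excluded:
        logger.info("consensus_table: %d molecule(s) ambiguous and excluded", n_excluded)
    return dict(table)


def usable_calls(table: Mapping[str, ConsensusCall]) -> dict[str, Direction]:
    """Reduce one class's consensus table to a molecule → direction map,
    dropping ambiguous calls (the form every downstream stage consumes)."""
    return {
        mol: Direction(call.direction.value)
        for mol, call in table.items()
        if call.usable
    }
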