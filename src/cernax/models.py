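"""Core record types shared across the pipeline stages.

Every identifier stored in these records is expected to be in canonical
form (see :func:`cernax.catalog_io.normalize_id`): upper-case gene /
protein / lncRNA symbols and ``hsa-miR-…`` style miRNA ids. Downstream
joins are plain string joins, so canonicalisation at the boundary is what
makes the catalogs composable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class MoleculeClass(str, enum.Enum):
    """The four molecular layers the evidence tables distinguish."""

    LNCRNA = "lncRNA"
    MIRNA = "miRNA"
    MRNA = "mRNA"
    PROTEIN = "protein"


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"


class ConsensusDirection(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    AMBIGUOUS = "ambiguous"


class Confidence(str, enum.Enum):
    """Interaction support: experimentally observed, or predicted
    (the latter must carry a TargetScan cumulative weighted context
    score, CWCS, so the high-confidence filter can be applied)."""

    OBSERVED = "observed"
    PREDICTED = "predicted"


class EvidenceTier(str, enum.Enum):
    """Functional-validation split used for miRNA-target and
    lncRNA-miRNA interactions: reporter assay / western blot / qPCR
    count as strong; high-throughput-only support is less strong."""

    STRONG = "strong"
    LESS_STRONG = "less_strong"


#: evidence methods that promote a miRNA-target edge to the strong tier
STRONG_EVIDENCE_METHODS = frozenset({"reporter_assay", "western_blot", "qpcr"})


@dataclass(frozen=True)
class ExpressionEvidence:
    """One study's up/down call for one molecule (optionally one transcript)."""

    molecule_id: str
    molecule_class: MoleculeClass
    study_id: str
    direction: Direction
    transcript_id: Optional[str] = None

    def key(self) -> tuple:
        return (self.molecule_id, self.molecule_class, self.study_id, self.transcript_id)


@dataclass(frozen=True)
class ConsensusCall:
    """Majority-rule direction for one molecule across its voting units.

    ``n_units`` counts the voting units at the outer level: studies, or
    transcript votes when the evidence is transcript-resolved. Ambiguous
    calls (exact ties) are retained for reporting but excluded from all
    downstream analysis.
    """

    molecule_id: str
    molecule_class: MoleculeClass
    direction: ConsensusDirection
    n_up: int
    n_down: int

    @property
    def n_units(self) -> int:
        return self.n_up + self.n_down

    @property
    def usable(self) -> bool:
        return self.direction is not ConsensusDirection.AMBIGUOUS


@dataclass(frozen=True)
class MirTargetEdge:
    """A miRNA → gene interaction with its confidence class and evidence.

    ``layers`` records which expression layer(s) supplied the target's
    differential-expression support (transcript and/or protein);
    ``evidence_methods`` holds the assay vocabulary used for tiering.
    """

    mirna_id: str
    target_symbol: str
    confidence: Confidence
    cwcs: Optional[float] = None
    layers: frozenset = field(default_factory=frozenset)
    evidence_methods: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.confidence is Confidence.PREDICTED and self.cwcs is None:
            raise ValueError(
                f"predicted edge {self.mirna_id}->{self.target_symbol} lacks a CWCS"
            )

    def key(self) -> tuple:
        return (self.mirna_id, self.target_symbol)


@dataclass(frozen=True)
class LncMirEdge:
    """A lncRNA – miRNA sponge interaction with its evidence tier."""

    lncrna_id: str
    mirna_id: str
    tier: EvidenceTier = EvidenceTier.STRONG

    def key(self) -> tuple:
        return (self.lncrna_id, self.mirna_id)


@dataclass(frozen=True)
class PpiEdge:
    """An undirected scored protein-protein edge (STRING export style,
    combined score on the 0-1000 integer scale). Stored with the
    lexicographically smaller symbol first."""

    protein_a: str
    protein_b: str
    combined_score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-loop on {self.protein_a}")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"combined_score {self.combined_score} outside [0, 1000]")
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    def key(self) -> tuple:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class PairedInteraction:
    """A miRNA-target edge retained by the inverse-expression pairing
    filter, annotated with both direction calls.

    ``dual_level`` marks targets differentially expressed at both the
    mRNA and the protein level; ``dual_concordant`` additionally
    requires the two calls to agree in sign (positive mRNA/protein
    correlation).
    """

    edge: MirTargetEdge
    mirna_direction: Direction
    target_direction: Direction
    dual_level: bool = False
    dual_concordant: bool = False
    discordant_layers: bool = False

    def __post_init__(self) -> None:
        if self.mirna_direction == self.target_direction:
            raise ValueError(
                f"pairing violated for {self.edge.mirna_id}->{self.edge.target_symbol}: "
                "miRNA and target share a direction"
            )
        if self.dual_concordant and not self.dual_level:
            raise ValueError("dual_concordant implies dual_level")


@dataclass(frozen=True)
class CeRNATriad:
    """An assembled lncRNA – miRNA – mRNA sponge axis.

    ``consistent`` encodes the ceRNA expectation: the sponge and the
    protected target move together while the miRNA moves against them.
    ``mirna_id`` is arm-resolved; ``arm_expanded`` is set when the arm
    was supplied by expansion rather than by the source catalog.
    """

    lncrna_id: str
    mirna_id: str
    target_symbol: str
    lnc_direction: Direction
    mir_direction: Direction
    target_direction: Direction
    mir_target_tier: EvidenceTier
    lnc_mir_tier: EvidenceTier
    arm_expanded: bool = False

    @property
    def consistent(self) -> bool:
        return (
            self.lnc_direction == self.target_direction
            and self.mir_direction != self.target_direction
        )
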