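"""Reading, validating, normalising and writing the tabular catalogs.

All input tables are UTF-8, tab-delimited, with a header row; lines
starting with ``#`` are comments. Identifiers are canonicalised at load
time so that every downstream join is a plain string join:

* gene / protein / lncRNA / mRNA symbols: trimmed and upper-cased;
* miRNA ids: ``hsa-`` prefix enforced, ``miR`` casing canonicalised,
  the ``-3p`` / ``-5p`` arm suffix preserved when present (and never
  guessed — arm expansion is an explicit operation in
  :mod:`cernax.cerna`).

An optional two-column alias table (raw TAB canonical) may be applied
before normalization to harmonise synonyms across source studies.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .models import (
    Confidence,
    Direction,
    EvidenceTier,
    ExpressionEvidence,
    GeneSet,
    LncMirEdge,
    MirTargetEdge,
    MoleculeClass,
    PpiEdge,
)

logger = logging.getLogger(__name__)

NETWORK_FORMATS = ("sif", "graphml", "tsv")


class CatalogError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# identifier and token normalization
# ---------------------------------------------------------------------------

def normalize_id(raw: str, molecule_class: MoleculeClass | str) -> str:
    """Return the canonical identifier for ``raw`` in ``molecule_class``.

    Idempotent: ``normalize_id(normalize_id(x), c) == normalize_id(x, c)``.

    Raises :class:`CatalogError` on an empty (after trimming) input.
    """
    molecule_class = MoleculeClass(molecule_class)
    s = raw.strip()
    if not s:
        raise CatalogError(f"empty identifier (raw input {raw!r})")
    if molecule_class is not MoleculeClass.MIRNA:
        return s.upper()

    low = s.lower()
    if low.startswith("hsa-"):
        low = low[4:]
    if low.startswith("mir-"):
        low = "miR-" + low[4:]
    elif low.startswith("mir") and not low.startswith("mir-"):
        # tolerate ids written without the hyphen, e.g. "miR125b"
        low = "miR-" + low[3:]
    return "hsa-" + low


def parse_direction(token: str) -> Direction:
    """Parse a heterogeneous direction token.

    Accepts ``up`` / ``down`` in any casing and signed numerics
    (``+1`` / ``-1`` / ``2.5`` …) mapped by sign.
    """
    t = str(token).strip()
    if t.lower() == "up":
        return Direction.UP
    if t.lower() == "down":
        return Direction.DOWN
    try:
        value = float(t)
    except ValueError:
        raise CatalogError(f"unknown direction token {token!r}") from None
    if value > 0:
        return Direction.UP
    if value < 0:
        return Direction.DOWN
    raise CatalogError(f"direction token {token!r} has no sign")


def load_alias_table(path: str | Path) -> dict:
    """Load a two-column raw→canonical alias TSV (no header)."""
    aliases: dict = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CatalogError(f"{path}:{line_no}: alias rows need exactly two columns")
        aliases[parts[0].strip()] = parts[1].strip()
    return aliases


def _apply_alias(raw: str, aliases: Optional[Mapping[str, str]]) -> str:
    if aliases:
        return aliases.get(raw.strip(), raw)
    return raw


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"input table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise CatalogError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing}")
    return df


def read_expression_table(
    path: str | Path,
    molecule_class: MoleculeClass | str | None = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> list[ExpressionEvidence]:
    """Load one expression-evidence table.

    Columns: ``molecule_id``, ``class`` (optional if ``molecule_class``
    given), ``study_id``, ``direction``, optional ``transcript_id``.
    Exact duplicate rows are collapsed with a logged warning.
    """
    required = ["molecule_id", "study_id", "direction"]
    df = _read_table(path, required)
    if molecule_class is None and "class" not in df.columns:
        raise CatalogError(f"{path}: missing required column(s) ['class']")

    records: dict = {}
    n_dups = 0
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            cls = MoleculeClass(molecule_class or row["class"])
            mol = normalize_id(_apply_alias(row["molecule_id"], aliases), cls)
            direction = parse_direction(row["direction"])
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        transcript = row.get("transcript_id")
        if pd.isna(transcript) or transcript is None or not str(transcript).strip():
            transcript = None
        else:
            transcript = str(transcript).strip()
        rec = ExpressionEvidence(mol, cls, str(row["study_id"]).strip(), direction, transcript)
        if rec.key() in records:
            if records[rec.key()].direction != rec.direction:
                raise CatalogError(
                    f"{path}:{line}: conflicting duplicate for {rec.key()} "
                    "(same study, opposite directions)"
                )
            n_dups += 1
        else:
            records[rec.key()] = rec
    if n_dups:
        logger.warning("%s: collapsed %d exact duplicate row(s)", path, n_dups)
    logger.info("%s: loaded %d evidence record(s)", path, len(records))
    return list(records.values())


def read_mir_target_table(
    path: str | Path, aliases: Optional[Mapping[str, str]] = None
) -> list[MirTargetEdge]:
    """Load a miRNA-target catalog.

    Columns: ``mirna_id``, ``target_symbol``, ``confidence``
    (observed/predicted), ``cwcs`` (required for predicted rows),
    ``evidence_methods`` (semicolon-separated, optional),
    ``layers`` (semicolon-separated subset of transcript/protein,
    optional — defaults to transcript).
    """
    df = _read_table(path, ["mirna_id", "target_symbol", "confidence"])
    edges: dict = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            mirna = normalize_id(_apply_alias(row["mirna_id"], aliases), MoleculeClass.MIRNA)
            target = normalize_id(_apply_alias(row["target_symbol"], aliases), MoleculeClass.MRNA)
            confidence = Confidence(str(row["confidence"]).strip().lower())
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        cwcs_raw = row.get("cwcs")
        cwcs = None if pd.isna(cwcs_raw) or str(cwcs_raw).strip() == "" else float(cwcs_raw)
        methods = _split_set(row.get("evidence_methods"))
        layers = _split_set(row.get("layers")) or frozenset({"transcript"})
        bad = layers - {"transcript", "protein"}
        if bad:
            raise CatalogError(f"{path}:{line}: unknown layer(s) {sorted(bad)}")
        try:
            edge = MirTargetEdge(mirna, target, confidence, cwcs, layers, methods)
        except ValueError as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        if edge.key() in edges:
            edges[edge.key()] = _merge_mir_edges(edges[edge.key()], edge)
        else:
            edges[edge.key()] = edge
    logger.info("%s: loaded %d miRNA-target edge(s)", path, len(edges))
    return list(edges.values())


def _merge_mir_edges(a: MirTargetEdge, b: MirTargetEdge) -> MirTargetEdge:
    """Union-merge two records of the same (miRNA, target) pair."""
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


def _split_set(value) -> frozenset:
    if value is None or pd.isna(value) or not str(value).strip():
        return frozenset()
    return frozenset(tok.strip().lower() for tok in str(value).split(";") if tok.strip())


def read_lnc_mir_table(
    path: str | Path, aliases: Optional[Mapping[str, str]] = None
) -> list[LncMirEdge]:
    """Load a lncRNA-miRNA catalog. Columns: ``lncrna_id``, ``mirna_id``,
    ``tier`` (strong/less_strong, optional — defaults to strong)."""
    df = _read_table(path, ["lncrna_id", "mirna_id"])
    edges: dict = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            lnc = normalize_id(_apply_alias(row["lncrna_id"], aliases), MoleculeClass.LNCRNA)
            mir = normalize_id(_apply_alias(row["mirna_id"], aliases), MoleculeClass.MIRNA)
            tier_raw = row.get("tier")
            tier = (
                EvidenceTier.STRONG
                if tier_raw is None or pd.isna(tier_raw) or not str(tier_raw).strip()
                else EvidenceTier(str(tier_raw).strip().lower())
            )
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        edge = LncMirEdge(lnc, mir, tier)
        edges[edge.key()] = edge
    logger.info("%s: loaded %d lncRNA-miRNA edge(s)", path, len(edges))
    return list(edges.values())


def read_ppi_table(
    path: str | Path, aliases: Optional[Mapping[str, str]] = None
) -> list[PpiEdge]:
    """Load a scored protein-protein edge table (STRING-export style).

    Scores given as 0-1 floats are rescaled to the 0-1000 integer
    convention; values in (1, 1000] are taken as already scaled.
    Duplicate pairs keep the maximum score.
    """
    df = _read_table(path, ["protein_a", "protein_b", "combined_score"])
    edges: dict = {}
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            a = normalize_id(_apply_alias(row["protein_a"], aliases), MoleculeClass.PROTEIN)
            b = normalize_id(_apply_alias(row["protein_b"], aliases), MoleculeClass.PROTEIN)
            score = _parse_ppi_score(row["combined_score"])
            edge = PpiEdge(a, b, score)
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        prev = edges.get(edge.key())
        if prev is None or edge.combined_score > prev.combined_score:
            edges[edge.key()] = edge
    logger.info("%s: loaded %d PPI edge(s)", path, len(edges))
    return list(edges.values())


def _parse_ppi_score(token) -> int:
    value = float(token)
    if 0.0 <= value <= 1.0:
        return round(value * 1000)
    if 1.0 < value <= 1000.0:
        return round(value)
    raise CatalogError(f"PPI score {token!r} outside [0, 1] and (1, 1000]")


def read_direction_table(
    path: str | Path, aliases: Optional[Mapping[str, str]] = None
) -> dict[MoleculeClass, dict[str, Direction]]:
    """Load a per-class molecule → direction table (the consensus
    command's output is one). Columns: ``molecule_id``, ``class``,
    ``direction``; rows whose direction is ``ambiguous`` are skipped."""
    df = _read_table(path, ["molecule_id", "class", "direction"])
    calls: dict[MoleculeClass, dict[str, Direction]] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        if str(row["direction"]).strip().lower() == "ambiguous":
            continue
        try:
            cls = MoleculeClass(row["class"])
            mol = normalize_id(_apply_alias(row["molecule_id"], aliases), cls)
            direction = parse_direction(row["direction"])
        except (CatalogError, ValueError) as exc:
            raise CatalogError(f"{path}:{line}: {exc}") from None
        calls.setdefault(cls, {})[mol] = direction
    return calls


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Load gene sets from a standard GMT file (name TAB description TAB
    members…); membership is upper-cased and deduplicated."""
    sets: list[GeneSet] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise CatalogError(f"{path}:{line_no}: GMT rows need name, description, members")
        members = frozenset(
            normalize_id(g, MoleculeClass.MRNA) for g in parts[2:] if g.strip()
        )
        if not members:
            raise CatalogError(f"{path}:{line_no}: gene set {parts[0]!r} has no members")
        sets.append(GeneSet(parts[0], members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na", *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# tabular writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_expression_table(records: Iterable[ExpressionEvidence], path: str | Path) -> None:
    rows = [
        {
            "molecule_id": r.molecule_id,
            "class": r.molecule_class.value,
            "study_id": r.study_id,
            "direction": r.direction.value,
            "transcript_id": r.transcript_id or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["molecule_id", "class", "study_id", "direction", "transcript_id"]
    ).to_csv(path, sep="\t", index=False)


def write_mir_target_table(edges: Iterable[MirTargetEdge], path: str | Path) -> None:
    rows = [
        {
            "mirna_id": e.mirna_id,
            "target_symbol": e.target_symbol,
            "confidence": e.confidence.value,
            "cwcs": "" if e.cwcs is None else e.cwcs,
            "evidence_methods": ";".join(sorted(e.evidence_methods)),
            "layers": ";".join(sorted(e.layers)),
        }
        for e in edges
    ]
    pd.DataFrame(
        rows,
        columns=["mirna_id", "target_symbol", "confidence", "cwcs", "evidence_methods", "layers"],
    ).to_csv(path, sep="\t", index=False)


def write_lnc_mir_table(edges: Iterable[LncMirEdge], path: str | Path) -> None:
    rows = [
        {"lncrna_id": e.lncrna_id, "mirna_id": e.mirna_id, "tier": e.tier.value}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["lncrna_id", "mirna_id", "tier"]).to_csv(
        path, sep="\t", index=False
    )


def write_ppi_table(edges: Iterable[PpiEdge], path: str | Path) -> None:
    rows = [
        {"protein_a": e.protein_a, "protein_b": e.protein_b, "combined_score": e.combined_score}
        for e in edges
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# network export (what Cytoscape imports)
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Export an attributed network as SIF, GraphML or edge-attribute TSV.

    SIF lines use the edge's ``relation`` attribute as the interaction
    token (default ``interacts``). GraphML exports are round-trip safe:
    reading the file back reproduces node/edge sets and attributes.
    """
    fmt = fmt.lower()
    if fmt not in NETWORK_FORMATS:
        raise CatalogError(
            f"unknown network format {fmt!r}; supported: {', '.join(NETWORK_FORMATS)}"
        )
    path = Path(path)
    if graph.number_of_nodes() == 0:
        logger.warning("writing an empty network to %s", path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        lines = []
        for u, v, data in graph.edges(data=True):
            lines.append(f"{u}\t{data.get('relation', 'interacts')}\t{v}")
        for node in graph.nodes:
            if graph.degree(node) == 0:
                lines.append(str(node))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:  # tsv
        attr_names = sorted({k for _, _, d in graph.edges(data=True) for k in d})
        header = ["source", "target", *attr_names]
        lines = ["\t".join(header)]
        for u, v, data in graph.edges(data=True):
            lines.append("\t".join([str(u), str(v), *(str(data.get(k, "")) for k in attr_names)]))
        path.write_text("\n".join(lines) + "\n")


def read_network(path: str | Path) -> nx.Graph:
    """Read back a GraphML export (the round-trip partner of
    :func:`write_network`)."""
    return nx.read_graphml(path)
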