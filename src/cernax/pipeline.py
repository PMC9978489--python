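"""End-to-end orchestration: consensus → pairing → hubs → ORA → triads.

``run_all`` executes the stages in order on the tables named in a
:class:`RunConfig`, writes each stage's artifact to the output
directory, and produces a count-driven summary (``summary.json`` plus a
human-readable ``summary.txt``): evidence rows in, usable consensus
calls, paired and integrated interactions, observed subset, hub genes,
top enriched set, anchors and triads. Stage outputs re-fed individually
through the per-stage CLI commands reproduce the same artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import catalog_io, cerna, consensus, enrich, netcent, pairing
from .cerna import DirectionCalls
from .models import Confidence, MoleculeClass

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """All inputs and thresholds for one pipeline run. Defaults are the
    study thresholds: CWCS ≤ −0.4, PPI combined score ≥ 900 (0.9),
    top-10 centrality lists, significance at 0.05."""

    expression: str
    mir_targets: str
    lnc_mir: str
    ppi: Optional[str] = None
    gene_sets: Optional[str] = None
    alias_table: Optional[str] = None
    cwcs_cutoff: float = Field(default=pairing.DEFAULT_CWCS_CUTOFF, le=0.0)
    ppi_min_score: int = Field(default=netcent.DEFAULT_MIN_SCORE, ge=0, le=1000)
    top_k: int = Field(default=netcent.DEFAULT_TOP_K, ge=1)
    restrict_ppi_to_observed: bool = True
    alpha: float = Field(default=enrich.DEFAULT_ALPHA, gt=0.0, lt=1.0)
    anchor_mode: Literal["auto", "hubs", "dual_concordant", "explicit"] = "auto"
    anchors: List[str] = Field(default_factory=list)
    network_format: Literal["sif", "graphml", "tsv"] = "graphml"
    seed: int = 0
    outdir: str = "cernax_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aliases = (
        catalog_io.load_alias_table(config.alias_table) if config.alias_table else None
    )
    summary: dict = {"config": config.model_dump()}

    # --- consensus -------------------------------------------------------
    try:
        evidence = catalog_io.read_expression_table(config.expression, aliases=aliases)
        table = consensus.consensus_table(evidence)
        calls = {cls: consensus.usable_calls(tab) for cls, tab in table.items()}
    except Exception as exc:
        raise StageError("consensus", exc) from exc
    _write_consensus(table, outdir / "consensus.tsv")
    summary["consensus"] = {
        "n_evidence_rows": len(evidence),
        "n_molecules": {cls.value: len(tab) for cls, tab in table.items()},
        "n_usable": {cls.value: len(c) for cls, c in calls.items()},
        "n_ambiguous_excluded": sum(
            len(tab) - len(calls[cls]) for cls, tab in table.items()
        ),
    }
    mirna_calls = calls.get(MoleculeClass.MIRNA, {})
    mrna_calls = calls.get(MoleculeClass.MRNA, {})
    protein_calls = calls.get(MoleculeClass.PROTEIN, {})
    lnc_calls = calls.get(MoleculeClass.LNCRNA, {})

    # --- pairing and integration ----------------------------------------
    try:
        candidate_edges = catalog_io.read_mir_target_table(config.mir_targets, aliases=aliases)
        filtered = pairing.confidence_filter(candidate_edges, config.cwcs_cutoff)
        transcript_layer = pairing.expression_pair(filtered, mirna_calls, mrna_calls)
        protein_layer = pairing.expression_pair(filtered, mirna_calls, protein_calls)
        catalog = pairing.integrate_layers(
            transcript_layer, protein_layer, mrna_calls, protein_calls
        )
        observed, n_observed_targets = pairing.observed_subset(catalog)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("pairing", exc) from exc
    _write_catalog(catalog, outdir / "catalog.tsv")
    summary["pairing"] = {
        "n_candidate_edges": len(candidate_edges),
        "n_after_confidence_filter": len(filtered),
        "n_transcript_layer": len(transcript_layer),
        "n_protein_layer": len(protein_layer),
        "n_integrated": len(catalog),
        "n_observed": len(observed),
        "n_predicted": len(catalog) - len(observed),
        "n_observed_targets": n_observed_targets,
        "n_dual_level": int(sum(p.dual_level for p in catalog)),
        "n_dual_concordant": int(sum(p.dual_concordant for p in catalog)),
    }
    observed_targets = sorted({p.edge.target_symbol for p in observed})

    # --- hubs on the observed-target subgraph ---------------------------
    hubs: list[str] = []
    if config.ppi:
        try:
            ppi_edges = catalog_io.read_ppi_table(config.ppi, aliases=aliases)
            if config.restrict_ppi_to_observed and observed_targets:
                keep = set(observed_targets)
                ppi_edges = [
                    e for e in ppi_edges if e.protein_a in keep and e.protein_b in keep
                ]
            graph = netcent.build_graph(ppi_edges, config.ppi_min_score)
            hub_result = netcent.hub_intersection(graph, config.top_k)
            hubs = hub_result.hubs
        except StageError:
            raise
        except Exception as exc:
            raise StageError("netcent", exc) from exc
        pd.DataFrame(netcent.centrality_table(graph)).to_csv(
            outdir / "centrality.tsv", sep="\t", index=False
        )
        (outdir / "hubs.txt").write_text("\n".join(hubs) + ("\n" if hubs else ""))
        summary["netcent"] = {
            "n_nodes": len(graph.adj),
            "n_edges": graph.n_edges,
            "rankings": hub_result.rankings,
            "hubs": hubs,
        }

    # --- over-representation --------------------------------------------
    if config.gene_sets:
        try:
            collection = catalog_io.read_gmt(config.gene_sets)
            results = enrich.run_ora(observed_targets, collection, alpha=config.alpha)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrich", exc) from exc
        _write_enrichment(results, outdir / "enrichment.tsv")
        summary["enrich"] = {
            "n_sets": len(results),
            "n_significant_p": int(sum(r.significant_p for r in results)),
            "n_significant_fdr": int(sum(r.significant_fdr for r in results)),
            "top_set": results[0].set_name if results else None,
            "top_p": results[0].p_value if results else None,
        }

    # --- triad assembly --------------------------------------------------
    try:
        lnc_catalog = catalog_io.read_lnc_mir_table(config.lnc_mir, aliases=aliases)
        anchors = _select_anchors(config, hubs, catalog, mrna_calls, protein_calls)
        target_calls = dict(protein_calls)
        target_calls.update(mrna_calls)  # mRNA-class calls take precedence
        direction_calls = DirectionCalls(
            mirna=mirna_calls, target=target_calls, lncrna=lnc_calls
        )
        retained_edges = [p.edge for p in catalog]
        triads, empty_anchors = cerna.assemble_triads(
            anchors, retained_edges, lnc_catalog, direction_calls, config.cwcs_cutoff
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cerna", exc) from exc
    _write_triads(triads, outdir / "triads.tsv")
    if triads:
        cerna.export_cerna_network(
            triads,
            outdir / f"cerna_network.{config.network_format}",
            config.network_format,
        )
    summary["cerna"] = {
        "n_anchors": len(anchors),
        "anchors": sorted(anchors),
        "n_triads": len(triads),
        "anchors_without_triads": empty_anchors,
    }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (outdir / "summary.txt").write_text(_render_summary(summary))
    return summary


def _select_anchors(config, hubs, catalog, mrna_calls, protein_calls) -> list[str]:
    if config.anchor_mode == "explicit":
        if not config.anchors:
            raise ValueError("anchor_mode=explicit requires a non-empty anchors list")
        return sorted(set(config.anchors))
    dual = sorted({p.edge.target_symbol for p in catalog if p.dual_concordant})
    if config.anchor_mode == "hubs":
        selected = list(hubs)
    elif config.anchor_mode == "dual_concordant":
        selected = dual
    else:  # auto: hub genes union dual-concordant targets
        selected = sorted(set(hubs) | set(dual))
    # anchors must have a direction call to be assembled
    callable_targets = set(mrna_calls) | set(protein_calls)
    return [a for a in selected if a in callable_targets]


def _write_consensus(table, path) -> None:
    rows = [
        {
            "molecule_id": call.molecule_id,
            "class": cls.value,
            "direction": call.direction.value,
            "n_up": call.n_up,
            "n_down": call.n_down,
        }
        for cls, tab in table.items()
        for call in tab.values()
    ]
    pd.DataFrame(
        rows, columns=["molecule_id", "class", "direction", "n_up", "n_down"]
    ).to_csv(path, sep="\t", index=False)


def _write_catalog(catalog, path) -> None:
    rows = [
        {
            "mirna_id": p.edge.mirna_id,
            "target_symbol": p.edge.target_symbol,
            "confidence": p.edge.confidence.value,
            "cwcs": "" if p.edge.cwcs is None else p.edge.cwcs,
            "evidence_methods": ";".join(sorted(p.edge.evidence_methods)),
            "layers": ";".join(sorted(p.edge.layers)),
            "mirna_direction": p.mirna_direction.value,
            "target_direction": p.target_direction.value,
            "dual_level": p.dual_level,
            "dual_concordant": p.dual_concordant,
        }
        for p in catalog
    ]
    pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "target_symbol", "confidence", "cwcs", "evidence_methods",
            "layers", "mirna_direction", "target_direction", "dual_level",
            "dual_concordant",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_enrichment(results, path) -> None:
    rows = [
        {
            "set_name": r.set_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_value": r.p_value,
            "neg_log10_p": r.neg_log10_p,
            "fdr": r.fdr,
            "significant_p": r.significant_p,
            "significant_fdr": r.significant_fdr,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "set_name", "k", "K", "n", "N", "p_value", "neg_log10_p", "fdr",
            "significant_p", "significant_fdr",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_triads(triads, path) -> None:
    rows = [
        {
            "lncrna_id": t.lncrna_id,
            "mirna_id": t.mirna_id,
            "target_symbol": t.target_symbol,
            "lnc_direction": t.lnc_direction.value,
            "mir_direction": t.mir_direction.value,
            "target_direction": t.target_direction.value,
            "mir_target_tier": t.mir_target_tier.value,
            "lnc_mir_tier": t.lnc_mir_tier.value,
            "arm_expanded": t.arm_expanded,
        }
        for t in triads
    ]
    pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mirna_id", "target_symbol", "lnc_direction",
            "mir_direction", "target_direction", "mir_target_tier",
            "lnc_mir_tier", "arm_expanded",
        ],
    ).to_csv(path, sep="\t", index=False)


def _render_summary(summary: dict) -> str:
    lines = ["cernax pipeline summary", "======================="]
    cons = summary.get("consensus", {})
    lines.append(f"evidence rows: {cons.get('n_evidence_rows')}")
    lines.append(f"molecules per class: {cons.get('n_molecules')}")
    lines.append(f"usable calls per class: {cons.get('n_usable')}")
    lines.append(f"ambiguous excluded: {cons.get('n_ambiguous_excluded')}")
    pair = summary.get("pairing", {})
    lines.append(
        "interactions: "
        f"{pair.get('n_candidate_edges')} candidates -> "
        f"{pair.get('n_after_confidence_filter')} confident -> "
        f"{pair.get('n_integrated')} integrated "
        f"({pair.get('n_observed')} observed + {pair.get('n_predicted')} predicted)"
    )
    lines.append(
        f"observed targets: {pair.get('n_observed_targets')} "
        f"(dual-level {pair.get('n_dual_level')}, "
        f"dual-concordant {pair.get('n_dual_concordant')})"
    )
    if "netcent" in summary:
        net = summary["netcent"]
        lines.append(
            f"PPI graph: {net['n_nodes']} nodes / {net['n_edges']} edges; "
            f"hubs: {', '.join(net['hubs']) or '(none)'}"
        )
    if "enrich" in summary:
        enr = summary["enrich"]
        lines.append(
            f"enrichment: top set {enr['top_set']} (p = {enr['top_p']:.3g}); "
            f"{enr['n_significant_p']} set(s) at p < alpha"
        )
    cer = summary.get("cerna", {})
    lines.append(
        f"triads: {cer.get('n_triads')} across {cer.get('n_anchors')} anchor(s); "
        f"anchors without triads: {', '.join(cer.get('anchors_without_triads', [])) or '(none)'}"
    )
    return "\n".join(lines) + "\n"
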