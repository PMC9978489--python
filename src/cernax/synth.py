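"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the literature-curated inputs
the pipeline consumes — per-study up/down calls with a configurable
flip-noise rate, interaction catalogs containing direction-consistent
sponge axes planted among adversarial decoys, a scored PPI edge table
with planted high-degree hubs, and gene-set collections with one
planted enriched set — without emulating expression magnitudes or count
matrices (the pipeline consumes directions only).

Decoy interaction edges are adversarial by category: each one violates
exactly one retention predicate (same-sign directions, a weak predicted
context score, or a missing lncRNA partner), so every filter has
dedicated violators and recovery of the planted axes is exact under the
true directions.

One integer seed drives all generators through numpy's splittable
``SeedSequence``, so a bundle is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import catalog_io
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


@dataclass
class GroundTruth:
    """Manifest of everything the generators planted."""

    seed: int
    true_directions: dict = field(default_factory=dict)  # molecule id -> Direction
    planted_axes: list = field(default_factory=list)  # (lncRNA, miRNA arm, target)
    planted_hubs: set = field(default_factory=set)
    planted_enriched_set: Optional[str] = None
    decoys: list = field(default_factory=list)  # {"edge": (mir, target), "violates": ...}

    def __post_init__(self) -> None:
        for lnc, mir, target in self.planted_axes:
            if not self._axis_consistent(lnc, mir, target):
                raise ValueError(f"planted axis ({lnc}, {mir}, {target}) is not consistent")
        if len(self.planted_hubs) != len(set(self.planted_hubs)):
            raise ValueError("planted hubs must be distinct")

    def _axis_consistent(self, lnc: str, mir: str, target: str) -> bool:
        d = self.true_directions
        if not {lnc, mir, target} <= set(d):
            return False
        return d[lnc] == d[target] and d[mir] != d[target]

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "true_directions": {m: d.value for m, d in self.true_directions.items()},
            "planted_axes": [list(a) for a in self.planted_axes],
            "planted_hubs": sorted(self.planted_hubs),
            "planted_enriched_set": self.planted_enriched_set,
            "decoys": self.decoys,
        }


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

def gen_expression_studies(
    molecules: Mapping[str, MoleculeClass],
    n_studies: int,
    flip_noise: float,
    seed: int,
    true_directions: Optional[Mapping[str, Direction]] = None,
) -> tuple[list[ExpressionEvidence], dict]:
    """Per-study direction calls: each study reports each molecule's true
    direction, flipped independently with probability ``flip_noise``.

    Returns the evidence list and the true-direction map (generated
    uniformly at random when not supplied). ``flip_noise`` must be below
    0.5 — at or above it the majority rule carries no signal.
    """
    if not 0.0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must lie in [0, 0.5)")
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    rng_dirs, rng_flips = _spawn(seed, 2)

    if true_directions is None:
        truth = {
            m: Direction.UP if rng_dirs.random() < 0.5 else Direction.DOWN
            for m in molecules
        }
    else:
        truth = dict(true_directions)
        missing = set(molecules) - set(truth)
        if missing:
            raise ValueError(f"no true direction for molecule(s) {sorted(missing)[:5]}…")

    flip = {Direction.UP: Direction.DOWN, Direction.DOWN: Direction.UP}
    evidence = []
    for mol in sorted(molecules):
        for study in range(1, n_studies + 1):
            d = truth[mol]
            if rng_flips.random() < flip_noise:
                d = flip[d]
            evidence.append(
                ExpressionEvidence(mol, molecules[mol], f"study_{study:02d}", d)
            )
    return evidence, truth


# ---------------------------------------------------------------------------
# interaction catalogs with planted axes and adversarial decoys
# ---------------------------------------------------------------------------

DECOY_CATEGORIES = ("wrong_sign", "weak_cwcs", "no_lnc_partner")


def gen_interaction_catalogs(
    truth: GroundTruth, n_decoy_edges: int, seed: int
) -> tuple[list[MirTargetEdge], list[LncMirEdge]]:
    """Build miRNA-target and lncRNA-miRNA catalogs around the planted axes.

    Planted axes become observed, strong-evidence, inverse-direction
    edges with a sponge partner. Decoys cycle through the violation
    categories; each decoy's molecules receive true directions (added to
    the truth manifest) chosen so that exactly one retention predicate
    fails, and the manifest records which.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    strong = frozenset({"reporter_assay"})

    mir_catalog: dict = {}
    lnc_catalog: dict = {}
    for lnc, mir, target in truth.planted_axes:
        edge = MirTargetEdge(
            mir, target, Confidence.OBSERVED, None, frozenset({"transcript"}), strong
        )
        mir_catalog[edge.key()] = edge
        sponge = LncMirEdge(lnc, mir, EvidenceTier.STRONG)
        lnc_catalog[sponge.key()] = sponge

    def rand_dir() -> Direction:
        return Direction.UP if rng.random() < 0.5 else Direction.DOWN

    flip = {Direction.UP: Direction.DOWN, Direction.DOWN: Direction.UP}
    for i in range(n_decoy_edges):
        category = DECOY_CATEGORIES[i % len(DECOY_CATEGORIES)]
        mir = f"hsa-miR-{9000 + i}-5p"
        target = f"DECOY{i:04d}"
        t_dir = rand_dir()
        truth.true_directions[target] = t_dir
        if category == "wrong_sign":
            truth.true_directions[mir] = t_dir  # same sign: pairing filter drops it
            edge = MirTargetEdge(
                mir, target, Confidence.OBSERVED, None, frozenset({"transcript"}), strong
            )
            lnc = f"LNCDECOY{i:04d}"
            truth.true_directions[lnc] = t_dir
            lnc_catalog[(lnc, mir)] = LncMirEdge(lnc, mir, EvidenceTier.STRONG)
        elif category == "weak_cwcs":
            truth.true_directions[mir] = flip[t_dir]
            # predicted with CWCS above the -0.4 cutoff: confidence filter drops it
            edge = MirTargetEdge(
                mir,
                target,
                Confidence.PREDICTED,
                float(rng.uniform(-0.39, -0.05)),
                frozenset({"transcript"}),
                frozenset(),
            )
            lnc = f"LNCDECOY{i:04d}"
            truth.true_directions[lnc] = t_dir
            lnc_catalog[(lnc, mir)] = LncMirEdge(lnc, mir, EvidenceTier.STRONG)
        else:  # no_lnc_partner: survives pairing and confidence, finds no sponge
            truth.true_directions[mir] = flip[t_dir]
            edge = MirTargetEdge(
                mir, target, Confidence.OBSERVED, None, frozenset({"transcript"}), strong
            )
        mir_catalog[edge.key()] = edge
        truth.decoys.append({"edge": [mir, target], "violates": category})
    return list(mir_catalog.values()), list(lnc_catalog.values())


# ---------------------------------------------------------------------------
# PPI with planted hubs
# ---------------------------------------------------------------------------

def gen_ppi(
    n_background: int,
    background_edge_prob: float,
    n_hubs: int,
    hub_degree: int,
    seed: int,
    n_subthreshold: Optional[int] = None,
) -> tuple[list[PpiEdge], GroundTruth]:
    """Erdős–Rényi background (scores ≥ 900) plus hubs wired to
    ``hub_degree`` random background nodes, and sub-threshold decoy
    edges (scores < 900) so the score filter is exercised.

    Requires ``hub_degree ≥ 4 · n_background · background_edge_prob`` so
    the hubs stand clear of the background degree distribution.
    """
    if hub_degree < 4 * n_background * background_edge_prob:
        raise ValueError(
            "hub_degree must be at least 4x the expected background degree "
            f"({4 * n_background * background_edge_prob:.1f})"
        )
    if hub_degree > n_background:
        raise ValueError("hub_degree cannot exceed the number of background nodes")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    background = [f"BG{i:04d}" for i in range(n_background)]
    hubs = [f"HUB{i:02d}" for i in range(n_hubs)]
    edges: dict = {}

    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < background_edge_prob:
                e = PpiEdge(background[i], background[j], int(rng.integers(900, 1001)))
                edges[e.key()] = e
    for hub in hubs:
        partners = rng.choice(n_background, size=hub_degree, replace=False)
        for j in partners:
            e = PpiEdge(hub, background[j], int(rng.integers(900, 1001)))
            edges[e.key()] = e

    n_sub = n_background // 2 if n_subthreshold is None else n_subthreshold
    added = 0
    while added < n_sub:
        i, j = rng.integers(0, n_background, size=2)
        if i == j:
            continue
        e = PpiEdge(background[i], background[j], int(rng.integers(100, 900)))
        if e.key() in edges:
            continue
        edges[e.key()] = e
        added += 1

    truth = GroundTruth(seed=int(seed), planted_hubs=set(hubs))
    return list(edges.values()), truth


# ---------------------------------------------------------------------------
# gene sets with one planted enrichment
# ---------------------------------------------------------------------------

def gen_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    planted_query_overlap: int,
    seed: int,
    set_size: int = 40,
    query_size: Optional[int] = None,
) -> tuple[list[GeneSet], list[str], str]:
    """A collection with one planted set sharing ``planted_query_overlap``
    genes with the generated query, among random same-size sets.

    Returns ``(collection, query, planted_set_name)``. The generated
    sizes put the planted set's hypergeometric p far below 1e-4.
    """
    universe = list(dict.fromkeys(universe))
    if query_size is None:
        query_size = max(2 * planted_query_overlap, planted_query_overlap + 5)
    if planted_query_overlap > min(set_size, query_size):
        raise ValueError("overlap exceeds set/query size")
    if query_size + set_size - planted_query_overlap > len(universe):
        raise ValueError("universe too small for requested sizes")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    perm = list(rng.permutation(universe))
    shared = perm[:planted_query_overlap]
    query_only = perm[planted_query_overlap:query_size]
    rest = perm[query_size:]
    planted_members = shared + rest[: set_size - planted_query_overlap]
    planted_name = "PLANTED_PATHWAY"
    sets = [GeneSet(planted_name, frozenset(planted_members))]
    for i in range(n_sets - 1):
        members = rng.choice(universe, size=min(set_size, len(universe)), replace=False)
        sets.append(GeneSet(f"RANDOM_PATHWAY_{i:03d}", frozenset(members.tolist())))
    return sets, shared + query_only, planted_name


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

PRESETS: dict = {
    # molecule pool sizes, study design, planted structure
    "small": dict(
        n_mrna=60, n_mirna=20, n_lncrna=10, n_protein=30,
        n_studies=3, flip_noise=0.0, n_axes=3, n_decoys=9,
        ppi=dict(n_background=30, background_edge_prob=0.05, n_hubs=2, hub_degree=12),
        n_gene_sets=10, planted_overlap=10,
    ),
    "default": dict(
        n_mrna=300, n_mirna=80, n_lncrna=40, n_protein=120,
        n_studies=5, flip_noise=0.2, n_axes=5, n_decoys=30,
        ppi=dict(n_background=60, background_edge_prob=0.05, n_hubs=3, hub_degree=30),
        n_gene_sets=20, planted_overlap=25,
    ),
    "stress": dict(
        n_mrna=2000, n_mirna=400, n_lncrna=150, n_protein=500,
        n_studies=7, flip_noise=0.3, n_axes=12, n_decoys=120,
        ppi=dict(n_background=150, background_edge_prob=0.04, n_hubs=5, hub_degree=60),
        n_gene_sets=50, planted_overlap=30,
    ),
}


@dataclass
class SynthBundle:
    """All generated inputs plus their ground-truth manifest."""

    truth: GroundTruth
    evidence: list
    mir_catalog: list
    lnc_catalog: list
    ppi_edges: list
    gene_sets: list
    ora_query: list
    preset: str

    def write(self, outdir: str | Path) -> dict:
        """Write every input table plus ``truth.json``; returns the
        path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "mir_targets": outdir / "mir_targets.tsv",
            "lnc_mir": outdir / "lnc_mir.tsv",
            "ppi": outdir / "ppi.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "query": outdir / "ora_query.txt",
            "truth": outdir / "truth.json",
        }
        catalog_io.write_expression_table(self.evidence, paths["expression"])
        catalog_io.write_mir_target_table(self.mir_catalog, paths["mir_targets"])
        catalog_io.write_lnc_mir_table(self.lnc_catalog, paths["lnc_mir"])
        catalog_io.write_ppi_table(self.ppi_edges, paths["ppi"])
        catalog_io.write_gmt(self.gene_sets, paths["gene_sets"])
        paths["query"].write_text("\n".join(self.ora_query) + "\n")
        paths["truth"].write_text(json.dumps(self.truth.to_json(), indent=2))
        paths["config"] = outdir / "run.yaml"
        from .pipeline import RunConfig

        RunConfig(
            expression=str(paths["expression"]),
            mir_targets=str(paths["mir_targets"]),
            lnc_mir=str(paths["lnc_mir"]),
            ppi=str(paths["ppi"]),
            gene_sets=str(paths["gene_sets"]),
            # the generated PPI table is already the network of interest
            restrict_ppi_to_observed=False,
            seed=self.truth.seed,
            outdir=str(outdir / "out"),
        ).to_yaml(paths["config"])
        return {k: str(v) for k, v in paths.items()}


def generate_bundle(seed: int, preset: str = "default") -> SynthBundle:
    """Generate a complete, internally consistent input bundle."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    seeds = np.random.SeedSequence(seed).spawn(8)
    rng = np.random.default_rng(seeds[0])

    mrnas = [f"GENE{i:04d}" for i in range(p["n_mrna"])]
    mirnas = [f"hsa-miR-{100 + i}-{'5p' if i % 2 else '3p'}" for i in range(p["n_mirna"])]
    lncrnas = [f"LNC{i:03d}" for i in range(p["n_lncrna"])]
    # axis targets are measured at the protein level too, so they become
    # dual-level anchors; the rest of the protein pool is a random draw
    axis_targets = mrnas[: p["n_axes"]]
    others = [m for m in mrnas if m not in axis_targets]
    proteins = axis_targets + list(
        rng.choice(others, size=p["n_protein"] - len(axis_targets), replace=False)
    )

    # plant sponge axes on disjoint molecule triples
    axes = []
    truth_dirs: dict = {}
    flip = {Direction.UP: Direction.DOWN, Direction.DOWN: Direction.UP}
    for i in range(p["n_axes"]):
        lnc, mir, target = lncrnas[i], mirnas[i], mrnas[i]
        t_dir = Direction.UP if rng.random() < 0.5 else Direction.DOWN
        truth_dirs[target] = t_dir
        truth_dirs[mir] = flip[t_dir]
        truth_dirs[lnc] = t_dir
    axes = [(lncrnas[i], mirnas[i], mrnas[i]) for i in range(p["n_axes"])]
    for mol in mrnas + mirnas + lncrnas:
        truth_dirs.setdefault(
            mol, Direction.UP if rng.random() < 0.5 else Direction.DOWN
        )

    truth = GroundTruth(seed=int(seed), true_directions=truth_dirs, planted_axes=axes)
    mir_catalog, lnc_catalog = gen_interaction_catalogs(
        truth, p["n_decoys"], seed=int(seeds[1].generate_state(1)[0] % 2**31)
    )

    molecule_classes: dict = {}
    for m in mrnas:
        molecule_classes[m] = MoleculeClass.MRNA
    for m in mirnas:
        molecule_classes[m] = MoleculeClass.MIRNA
    for m in lncrnas:
        molecule_classes[m] = MoleculeClass.LNCRNA
    for d in truth.decoys:  # decoy molecules also get expression evidence
        mir, target = d["edge"]
        molecule_classes[mir] = MoleculeClass.MIRNA
        molecule_classes[target] = MoleculeClass.MRNA
    for lnc in {e.lncrna_id for e in lnc_catalog}:
        molecule_classes.setdefault(lnc, MoleculeClass.LNCRNA)

    evidence, _ = gen_expression_studies(
        molecule_classes,
        p["n_studies"],
        p["flip_noise"],
        seed=int(seeds[2].generate_state(1)[0] % 2**31),
        true_directions=truth.true_directions,
    )
    protein_evidence, _ = gen_expression_studies(
        {m: MoleculeClass.PROTEIN for m in proteins},
        p["n_studies"],
        p["flip_noise"],
        seed=int(seeds[3].generate_state(1)[0] % 2**31),
        true_directions=truth.true_directions,
    )
    evidence += protein_evidence

    ppi_edges, ppi_truth = gen_ppi(
        seed=int(seeds[4].generate_state(1)[0] % 2**31), **p["ppi"]
    )
    truth.planted_hubs = ppi_truth.planted_hubs

    gene_sets, query, planted_name = gen_gene_sets(
        mrnas,
        p["n_gene_sets"],
        p["planted_overlap"],
        seed=int(seeds[5].generate_state(1)[0] % 2**31),
    )
    truth.planted_enriched_set = planted_name

    return SynthBundle(
        truth=truth,
        evidence=evidence,
        mir_catalog=mir_catalog,
        lnc_catalog=lnc_catalog,
        ppi_edges=ppi_edges,
        gene_sets=gene_sets,
        ora_query=query,
        preset=preset,
    )
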