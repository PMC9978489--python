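"""Arm expansion, evidence tiering and triad assembly with a brute oracle."""

import numpy as np
import pytest

from cernax import datasets
from cernax.cerna import (
    DirectionCalls,
    assemble_triads,
    expand_arms,
    export_cerna_network,
    tier_mir_target,
    triads_to_network,
)
from cernax.catalog_io import read_network
from cernax.models import (
    CeRNATriad,
    Confidence,
    Direction,
    EvidenceTier,
    LncMirEdge,
    MirTargetEdge,
)
from cernax.pairing import confidence_filter

UP, DOWN = Direction.UP, Direction.DOWN


@pytest.mark.parametrize(
    "mirna, expected",
    [
        ("hsa-miR-34a-5p", {"hsa-miR-34a-5p"}),
        ("hsa-miR-125b", {"hsa-miR-125b-3p", "hsa-miR-125b-5p"}),
        ("hsa-miR-1-3p", {"hsa-miR-1-3p"}),
    ],
)
def test_expand_arms(mirna, expected):
    assert expand_arms(mirna) == expected


def test_expand_arms_idempotent_on_outputs():
    for out in expand_arms("hsa-miR-125b"):
        assert expand_arms(out) == {out}


def _edge(mir, tgt, methods=(), conf=Confidence.OBSERVED, cwcs=None):
    return MirTargetEdge(
        mir, tgt, conf, cwcs, frozenset({"transcript"}), frozenset(methods)
    )


@pytest.mark.parametrize(
    "methods, tier",
    [
        (("reporter_assay", "microarray"), EvidenceTier.STRONG),
        (("western_blot",), EvidenceTier.STRONG),
        (("qpcr",), EvidenceTier.STRONG),
        (("clip_seq",), EvidenceTier.LESS_STRONG),
        ((), EvidenceTier.LESS_STRONG),
    ],
)
def test_tier_mir_target(methods, tier):
    assert tier_mir_target(_edge("hsa-miR-1-3p", "PTMA", methods)) is tier


# ---------------------------------------------------------------------------
# assembly on the packaged literature fixtures
# ---------------------------------------------------------------------------

def test_dual_level_fixture_yields_six_triads():
    """The EZH2/PTMA sponge catalog assembles into exactly six
    consistent triads spanning 3 lncRNAs, 3 miRNAs and 2 mRNAs."""
    mir_catalog, lnc_catalog, calls = datasets.load_gbc_dual_axes()
    triads, empty = assemble_triads(["EZH2", "PTMA"], mir_catalog, lnc_catalog, calls)
    assert len(triads) == 6
    assert empty == []
    assert all(t.consistent for t in triads)
    assert {(t.lncrna_id, t.mirna_id, t.target_symbol) for t in triads} == {
        ("TUG1", "hsa-miR-26a-5p", "EZH2"),
        ("MALAT1", "hsa-miR-26a-5p", "EZH2"),
        ("NEAT1", "hsa-miR-101-3p", "EZH2"),
        ("MALAT1", "hsa-miR-101-3p", "EZH2"),
        ("TUG1", "hsa-miR-1-3p", "PTMA"),
        ("MALAT1", "hsa-miR-1-3p", "PTMA"),
    }


def test_hub_fixture_strong_tp53_regulators():
    """Three functionally validated miRNAs regulate TP53 in the hub-axis
    catalog, and the arm-less miR-200a joins its sponges via expansion."""
    mir_catalog, lnc_catalog, calls = datasets.load_gbc_hub_axes()
    strong_tp53 = [
        e
        for e in mir_catalog
        if e.target_symbol == "TP53" and tier_mir_target(e) is EvidenceTier.STRONG
    ]
    assert len(strong_tp53) == 3
    triads, empty = assemble_triads(
        ["TP53", "CCND1", "CTNNB1"], mir_catalog, lnc_catalog, calls
    )
    assert empty == []
    ctnnb1 = [t for t in triads if t.target_symbol == "CTNNB1"]
    assert {t.mirna_id for t in ctnnb1} == {"hsa-miR-200a-3p"}
    assert all(t.arm_expanded for t in ctnnb1)


def test_inconsistent_lncrna_direction_excluded():
    mir = [_edge("hsa-miR-1-3p", "PTMA", ("reporter_assay",))]
    lnc = [LncMirEdge("TUG1", "hsa-miR-1-3p")]
    calls = DirectionCalls(
        mirna={"hsa-miR-1-3p": DOWN},
        target={"PTMA": UP},
        lncrna={"TUG1": DOWN},  # sponge moving against the target
    )
    triads, empty = assemble_triads(["PTMA"], mir, lnc, calls)
    assert triads == [] and empty == ["PTMA"]


def test_anchor_without_call_raises():
    with pytest.raises(ValueError, match="TAGLN"):
        assemble_triads(["TAGLN"], [], [], DirectionCalls())


def test_arm_fallback_direction_lookup():
    """An arm-less expression call covers both mature arms."""
    calls = DirectionCalls(mirna={"hsa-miR-200a": DOWN})
    assert calls.mirna_direction("hsa-miR-200a-3p") is DOWN
    assert calls.mirna_direction("hsa-miR-200a-5p") is DOWN
    assert calls.mirna_direction("hsa-miR-1-3p") is None


# ---------------------------------------------------------------------------
# brute-force oracle on random instances
# ---------------------------------------------------------------------------

def brute_triads(anchors, mir_catalog, lnc_catalog, calls, cwcs_cutoff=-0.4):
    out = set()
    for anchor in anchors:
        for e in mir_catalog:
            if e.target_symbol != anchor:
                continue
            if e.confidence is Confidence.PREDICTED and (
                e.cwcs is None or e.cwcs > cwcs_cutoff
            ):
                continue
            mir_dir = calls.mirna_direction(e.mirna_id)
            tgt_dir = calls.target.get(anchor)
            if mir_dir is None or tgt_dir is None or mir_dir == tgt_dir:
                continue
            for arm in expand_arms(e.mirna_id):
                for le in lnc_catalog:
                    if le.mirna_id != arm:
                        continue
                    lnc_dir = calls.lncrna.get(le.lncrna_id)
                    if lnc_dir is None or lnc_dir != tgt_dir:
                        continue
                    out.add((le.lncrna_id, arm, anchor))
    return out


def _random_instance(rng):
    mirnas = [f"hsa-miR-{i}" + rng.choice(["", "-3p", "-5p"]) for i in range(8)]
    targets = [f"G{i}" for i in range(6)]
    lncs = [f"L{i}" for i in range(5)]
    mir_catalog = {}
    for _ in range(20):
        predicted = rng.random() < 0.4
        e = MirTargetEdge(
            mirnas[rng.integers(len(mirnas))],
            targets[rng.integers(len(targets))],
            Confidence.PREDICTED if predicted else Confidence.OBSERVED,
            float(rng.uniform(-0.8, -0.1)) if predicted else None,
            frozenset({"transcript"}),
            frozenset({"reporter_assay"}) if rng.random() < 0.5 else frozenset(),
        )
        mir_catalog[e.key()] = e
    mir_catalog = list(mir_catalog.values())
    # the sponge catalog is arm-resolved; edges are unique per pair
    lnc_catalog = {}
    for _ in range(15):
        base = mirnas[rng.integers(len(mirnas))]
        arms = sorted(expand_arms(base))
        arm = arms[rng.integers(len(arms))]
        e = LncMirEdge(lncs[rng.integers(len(lncs))], arm)
        lnc_catalog[e.key()] = e
    lnc_catalog = list(lnc_catalog.values())
    rand = lambda: UP if rng.random() < 0.5 else DOWN
    calls = DirectionCalls(
        mirna={m: rand() for m in mirnas},
        target={t: rand() for t in targets},
        lncrna={l: rand() for l in lncs},
    )
    return mir_catalog, lnc_catalog, calls, targets


def test_assembly_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(100):
        mir_catalog, lnc_catalog, calls, targets = _random_instance(rng)
        triads, _ = assemble_triads(targets, mir_catalog, lnc_catalog, calls)
        got = {(t.lncrna_id, t.mirna_id, t.target_symbol) for t in triads}
        assert got == brute_triads(targets, mir_catalog, lnc_catalog, calls)
        assert len(got) == len(triads)  # no duplicate triads


def test_sign_symmetry_of_consistency():
    """Flipping every direction call leaves the consistent set unchanged."""
    rng = np.random.default_rng(17)
    flip = {UP: DOWN, DOWN: UP}
    for _ in range(20):
        mir_catalog, lnc_catalog, calls, targets = _random_instance(rng)
        flipped = DirectionCalls(
            mirna={m: flip[d] for m, d in calls.mirna.items()},
            target={t: flip[d] for t, d in calls.target.items()},
            lncrna={l: flip[d] for l, d in calls.lncrna.items()},
        )
        a, _ = assemble_triads(targets, mir_catalog, lnc_catalog, calls)
        b, _ = assemble_triads(targets, mir_catalog, lnc_catalog, flipped)
        key = lambda ts: {(t.lncrna_id, t.mirna_id, t.target_symbol) for t in ts}
        assert key(a) == key(b)


def test_removing_lncrna_never_increases_triads():
    rng = np.random.default_rng(23)
    mir_catalog, lnc_catalog, calls, targets = _random_instance(rng)
    full, _ = assemble_triads(targets, mir_catalog, lnc_catalog, calls)
    lncs = {e.lncrna_id for e in lnc_catalog}
    for drop in lncs:
        reduced = [e for e in lnc_catalog if e.lncrna_id != drop]
        fewer, _ = assemble_triads(targets, mir_catalog, reduced, calls)
        assert len(fewer) <= len(full)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def test_single_triad_network_attributes(tmp_path):
    triad = CeRNATriad(
        "TUG1", "hsa-miR-1-3p", "PTMA", UP, DOWN, UP,
        EvidenceTier.STRONG, EvidenceTier.STRONG,
    )
    g = triads_to_network([triad])
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
    assert g.nodes["TUG1"]["node_class"] == "lncRNA"
    assert g.nodes["hsa-miR-1-3p"]["direction"] == "down"
    assert g.edges["TUG1", "hsa-miR-1-3p"]["relation"] == "sponges"
    assert g.edges["hsa-miR-1-3p", "PTMA"]["evidence_tier"] == "strong"


def test_six_triad_fixture_network_shape_and_round_trip(tmp_path):
    mir_catalog, lnc_catalog, calls = datasets.load_gbc_dual_axes()
    triads, _ = assemble_triads(["EZH2", "PTMA"], mir_catalog, lnc_catalog, calls)
    out = tmp_path / "net.graphml"
    g = export_cerna_network(triads, out, "graphml")
    by_class = {}
    for _, data in g.nodes(data=True):
        by_class[data["node_class"]] = by_class.get(data["node_class"], 0) + 1
    assert by_class == {"lncRNA": 3, "miRNA": 3, "mRNA": 2}
    back = read_network(out)
    assert set(back.nodes) == set(g.nodes) and set(back.edges) == set(g.edges)
    assert dict(back.nodes["EZH2"]) == dict(g.nodes["EZH2"])


def test_export_requires_triads(tmp_path):
    with pytest.raises(ValueError):
        export_cerna_network([], tmp_path / "x.graphml")
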