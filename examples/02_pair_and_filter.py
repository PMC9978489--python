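"""Inverse-expression pairing and the high-confidence filter.

A miRNA-target edge survives only if the two molecules move in opposite
directions and the interaction is experimentally observed or predicted
with a TargetScan context score (CWCS) of -0.4 or lower.
"""

from cernax import (
    Confidence,
    Direction,
    MirTargetEdge,
    confidence_filter,
    expression_pair,
    integrate_layers,
    observed_subset,
)

edges = [
    MirTargetEdge("hsa-miR-34a-5p", "TP53", Confidence.OBSERVED),
    MirTargetEdge("hsa-miR-34a-5p", "MYC", Confidence.PREDICTED, cwcs=-0.55),
    MirTargetEdge("hsa-miR-34a-5p", "CDK4", Confidence.PREDICTED, cwcs=-0.2),  # too weak
    MirTargetEdge("hsa-miR-21-5p", "PTEN", Confidence.OBSERVED),  # same sign below
]
mirna_calls = {"hsa-miR-34a-5p": Direction.DOWN, "hsa-miR-21-5p": Direction.UP}
mrna_calls = {"TP53": Direction.UP, "MYC": Direction.UP, "CDK4": Direction.UP,
              "PTEN": Direction.UP}
protein_calls = {"TP53": Direction.UP}

confident = confidence_filter(edges)
paired = expression_pair(confident, mirna_calls, mrna_calls)
catalog = integrate_layers(paired, [], mrna_calls, protein_calls)
observed, n_targets = observed_subset(catalog)

print(f"{len(edges)} candidates -> {len(confident)} confident -> {len(catalog)} paired")
for p in catalog:
    print(
        f"  {p.edge.mirna_id} ({p.mirna_direction.value}) -> "
        f"{p.edge.target_symbol} ({p.target_direction.value}) "
        f"[{p.edge.confidence.value}, dual_level={p.dual_level}]"
    )
print(f"observed subset: {len(observed)} interaction(s), {n_targets} distinct target(s)")
# CDK4 fell to the CWCS cutoff and PTEN to the same-sign rule; TP53,
# called up at both mRNA and protein level, is flagged dual-level.
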