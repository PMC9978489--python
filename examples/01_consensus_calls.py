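"""Majority-rule direction consensus across studies.

Three studies vote on each molecule; a molecule is called up or down
only when strictly more than half agree, and an exact split is flagged
ambiguous and excluded downstream.
"""

from cernax import ExpressionEvidence, MoleculeClass, Direction, consensus_table

evidence = []
votes = {
    "TP53": ["up", "up", "down"],       # 2/3 up -> up
    "CCND1": ["up", "down"],            # 1-1 split -> ambiguous
    "hsa-miR-34a-5p": ["down"],         # single study -> down
}
for molecule, directions in votes.items():
    cls = MoleculeClass.MIRNA if molecule.startswith("hsa-") else MoleculeClass.MRNA
    for i, d in enumerate(directions):
        evidence.append(ExpressionEvidence(molecule, cls, f"study_{i}", Direction(d)))

for cls, table in consensus_table(evidence).items():
    for call in table.values():
        print(
            f"{call.molecule_id:18s} [{cls.value:5s}] -> {call.direction.value:9s} "
            f"({call.n_up} up / {call.n_down} down)"
        )
# The ambiguous CCND1 call stays in the table for reporting but carries
# no direction into pairing or triad assembly.
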