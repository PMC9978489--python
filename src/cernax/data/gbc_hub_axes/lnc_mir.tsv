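# Literature-curated lncRNA sponges of the hub-gene regulating miRNAs.
lncrna_id	mirna_id	tier
MALAT1	hsa-miR-125b-5p	strong
TUG1	hsa-miR-34a-5p	strong
NEAT1	hsa-miR-34a-5p	strong
MALAT1	hsa-miR-34a-5p	strong
PVT1	hsa-miR-30a-5p	strong
NEAT1	hsa-miR-30a-5p	strong
MALAT1	hsa-miR-30a-5p	strong
H19	hsa-miR-193a-3p	strong
NEAT1	hsa-miR-193a-3p	strong
PVT1	hsa-miR-195-5p	strong
MALAT1	hsa-miR-195-5p	strong
H19	hsa-miR-200a-3p	strong
MALAT1	hsa-miR-200a-3p	strong
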