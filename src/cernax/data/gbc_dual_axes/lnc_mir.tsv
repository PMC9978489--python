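# Literature-curated lncRNA sponges of the EZH2/PTMA-regulating miRNAs.
lncrna_id	mirna_id	tier
TUG1	hsa-miR-26a-5p	strong
MALAT1	hsa-miR-26a-5p	strong
NEAT1	hsa-miR-101-3p	strong
MALAT1	hsa-miR-101-3p	strong
TUG1	hsa-miR-1-3p	strong
MALAT1	hsa-miR-1-3p	strong
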