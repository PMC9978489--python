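# Direction calls for the gallbladder-cancer hub-gene sponge axes
# (TP53 / CCND1 / CTNNB1). Interaction partners are literature-curated;
# the direction assignments are synthetic sponge-consistent choices
# (tumour genes up, their regulating miRNAs down, sponges up).
molecule_id	class	direction
TP53	mRNA	up
CCND1	mRNA	up
CTNNB1	mRNA	up
hsa-miR-125b-5p	miRNA	down
hsa-miR-34a-5p	miRNA	down
hsa-miR-30a-5p	miRNA	down
hsa-miR-193a-3p	miRNA	down
hsa-miR-195-5p	miRNA	down
hsa-miR-200a	miRNA	down
MALAT1	lncRNA	up
PVT1	lncRNA	up
H19	lncRNA	up
NEAT1	lncRNA	up
TUG1	lncRNA	up
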