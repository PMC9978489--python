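# Direction calls for the gallbladder-cancer sponge axes of the targets
# differentially expressed at both the mRNA and the protein level
# (EZH2, PTMA). Interaction partners are literature-curated; the
# direction assignments are synthetic sponge-consistent choices.
molecule_id	class	direction
EZH2	mRNA	up
PTMA	mRNA	up
hsa-miR-26a-5p	miRNA	down
hsa-miR-101-3p	miRNA	down
hsa-miR-1-3p	miRNA	down
TUG1	lncRNA	up
MALAT1	lncRNA	up
NEAT1	lncRNA	up
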