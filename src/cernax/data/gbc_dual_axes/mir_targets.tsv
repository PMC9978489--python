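# Literature-curated, functionally validated miRNA regulators of EZH2
# and PTMA in gallbladder cancer.
mirna_id	target_symbol	confidence	cwcs	evidence_methods	layers
hsa-miR-26a-5p	EZH2	observed		reporter_assay;western_blot;qpcr	transcript;protein
hsa-miR-101-3p	EZH2	observed		reporter_assay;western_blot	transcript;protein
hsa-miR-1-3p	PTMA	observed		reporter_assay	transcript;protein
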