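# Literature-curated miRNA regulators of the gallbladder-cancer hub
# genes TP53, CCND1 and CTNNB1; all functionally validated (strong tier).
mirna_id	target_symbol	confidence	cwcs	evidence_methods	layers
hsa-miR-125b-5p	TP53	observed		reporter_assay;western_blot	transcript
hsa-miR-34a-5p	TP53	observed		reporter_assay	transcript
hsa-miR-30a-5p	TP53	observed		reporter_assay	transcript
hsa-miR-193a-3p	CCND1	observed		reporter_assay	transcript
hsa-miR-195-5p	CCND1	observed		reporter_assay;qpcr	transcript
hsa-miR-200a	CTNNB1	observed		reporter_assay	transcript
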