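sample	gene	alteration_kind	label	strategy
S1	G1	BOTH	TSG	GENE_CANCER_SPECIFIC
S1	G2	MUTATION	OG	GENE_CANCER_SPECIFIC
S2	G1	MUTATION	TSG	GENE_CANCER_SPECIFIC
S2	G3	MUTATION	NEUTRAL	GENE_CANCER_SPECIFIC
S2	G4	MUTATION	UNLABELED	GENE_CANCER_SPECIFIC
S3	G5	MUTATION	UNLABELED	GENE_CANCER_SPECIFIC
S3	G6	CNV	UNLABELED	GENE_CANCER_SPECIFIC
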