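sample	gene	alteration_kind	label	strategy
S1	G1	MUTATION	TSG	MUTATION_EXACT_TSG_OG
S1	G2	MUTATION	OG	MUTATION_EXACT_TSG_OG
S2	G1	MUTATION	UNLABELED	MUTATION_EXACT_TSG_OG
S2	G3	MUTATION	NEUTRAL	MUTATION_EXACT_TSG_OG
S2	G4	MUTATION	UNLABELED	MUTATION_EXACT_TSG_OG
S3	G5	MUTATION	UNLABELED	MUTATION_EXACT_TSG_OG
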