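sample	gene	alteration_kind	label	strategy
S1	G1	MUTATION	DRIVER	MUTATION_EXACT_BINARY
S1	G2	MUTATION	DRIVER	MUTATION_EXACT_BINARY
S2	G1	MUTATION	UNLABELED	MUTATION_EXACT_BINARY
S2	G3	MUTATION	NEUTRAL	MUTATION_EXACT_BINARY
S2	G4	MUTATION	UNLABELED	MUTATION_EXACT_BINARY
S3	G5	MUTATION	DRIVER	MUTATION_EXACT_BINARY
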