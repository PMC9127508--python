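sample	gene	neigh_FC	neigh_normFC	neigh_CNV_FC	neigh_CNV_normFC
S1	G1	1.9999945899105036	1.9999945899105036	0	0
S1	G2	-1.9999783598448886	-1.9999783598448886	-1.9999783598448886	-1.9999783598448886
S2	G1	0	0	0	0
S2	G3	0	0	0	0
S2	G4	0	0	0	0
S3	G5	0	0	0	0
S3	G6	0	0	0	0
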