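# provenance: calibrated
# convention: raw-deflate-wbits=-15-level=1
read_length	threshold	sensitivity	specificity	background	seed
50	0.500000	1.0000	1.0000	uniform	20260928
75	0.506667	1.0000	1.0000	uniform	20260928
100	0.480000	1.0000	1.0000	uniform	20260928
124	0.467742	1.0000	0.9996	uniform	20260928
125	0.464000	1.0000	0.9998	uniform	20260928
150	0.446667	0.9998	0.9998	uniform	20260928
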