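# Published confusion counts for the eight consensus voting models
# (A-D: 1-4 of 5 functional predictors; A3-D3: same plus conservation
# and stability gates) evaluated on a clinical standard dataset of
# 50 pathogenic + 50 benign nsSNPs.
model	tp	fn	tn	fp
A	50	0	25	25
B	46	4	32	18
C	45	5	40	10
D	42	8	47	3
A3	48	2	40	10
B3	44	6	44	6
C3	39	11	46	4
D3	38	12	48	2
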