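case_study	cl	score	rank
CS1	2	0.858	1
CS2	3	0.798	2
CS3	4	0.602	3
CS4	5	0.481	4
CS5	6	0.236	5
CS6	7	0.186	6
CS7	8	0.123	7
CS8	9	0.070	8
CS9	10	0.0	9
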