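case_study	cl	FSI	PE	PC	MPC
CS1	2	0.482	0.578	0.607	0.215
CS2	3	0.543	0.886	0.482	0.224
CS3	4	0.588	0.117	0.373	0.164
CS4	5	0.632	0.139	0.304	0.130
CS5	6	0.333	0.157	0.246	0.095
CS6	7	0.364	0.172	0.215	0.085
CS7	8	0.340	0.185	0.190	0.075
CS8	9	0.328	0.197	0.165	0.061
CS9	10	0.267	0.209	0.153	0.059
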