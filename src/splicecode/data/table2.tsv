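class	enriched_ranks	depleted_ranks
APr-A3	11,19,26,27,28,30	2,3,8
APr-A5	None	None
APr-ME	None	None
APr-R	7,10,11,14,21,22,24,30,31,32,33	3,5,8
APr-S	7,33,42	5
APr-APA	None	None
A3-A3	None	None
A3-A5	None	None
A3-ME	None	None
A3-R	1,4	5
A3-S	2	3
A3-APA	None	None
A5-A3	11,14,28,30,34,42	2,3,5,7,8,10
A5-A5	4,33	3
A5-ME	None	None
A5-R	6,10,11,14,15,19,22,25,26,27,28,30,31,32,33,34	1,2,3,9
A5-S	11,12,41,42	1,8
A5-APA	None	None
ME-A3	None	None
ME-A5	None	None
ME-ME	None	None
ME-R	None	1
ME-S	None	None
ME-APA	None	None
R-A3	1,4,32	5,8,11,12,17
R-A5	None	None
R-ME	None	None
R-R	2,3,4,8,9,29,37	7,11,16,19,21,22,24,26,27,30,31,32,33,34,42
R-S	1,3,42	11
R-APA	1,7	4
S-A3	None	None
S-A5	13	None
S-ME	None	None
S-R	6,11,20,22,41	1,4
S-S	3,5,13,17,18	4,10,14,31
S-APA	3	None
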