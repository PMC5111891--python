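gene	ts	tv	syn	nonsyn
atpA	1	0	1	0
atpI	1	0	1	0
matK	0	1	0	1
ndhF	1	0	0	1
ndhI	0	1	0	1
psbC	0	1	1	0
rpoB	1	0	1	0
rpoC2	0	3	0	3
rps15	1	0	0	1
rps3	0	1	0	1
ycf1	1	2	1	2
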