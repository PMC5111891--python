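region	location	ha_base	hp_base
atpA	Coding	G	A
atpI	Coding	T	C
matK	Coding	C	A
ndhF	Coding	C	T
ndhI	Coding	G	T
psbC	Coding	A	C
rpoB	Coding	C	T
rpoC2	Coding	C	A
rpoC2	Coding	C	G
rpoC2	Coding	G	T
rps15	Coding	A	G
rps3	Coding	T	G
ycf1	Coding	A	G
ycf1	Coding	G	C
ycf1	Coding	G	T
atpB-rbcL	Intergenic	A	C
atpF-atpH	Intergenic	G	C
atpH-atpI	Intergenic	G	A
ndhF-rpl32	Intergenic	G	T
psaJ-rpl33	Intergenic	C	T
psaJ-rpl33	Intergenic	T	A
psbE-petL	Intergenic	C	A
psbM-trnD	Intergenic	A	G
rpl14-rpl16	Intergenic	T	G
rpl20-rps12	Intergenic	G	T
rpl33-rps18	Intergenic	T	C
rpoA-rps11	Intergenic	A	G
rpoA-rps11	Intergenic	T	C
rpoB-trnC	Intergenic	G	T
rpoB-trnC	Intergenic	T	G
rps18-rpl20	Intergenic	T	G
rps8-rpl14	Intergenic	G	A
trnG-trnR	Intergenic	A	C
trnH-psbA	Intergenic	T	G
trnK-matK	Intergenic	A	C
trnK-rps16	Intergenic	A	C
trnP-psaJ	Intergenic	C	T
trnP-psaJ	Intergenic	C	T
clpP	Intron	T	G
ndhA	Intron	T	C
rpl16	Intron	T	C
rps16	Intron	T	G
trnV	Intron	T	C
ycf3	Intron	T	C
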