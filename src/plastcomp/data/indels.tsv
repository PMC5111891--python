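region	location	klass	ha_seq	hp_seq	length	direction	flags
accD-psaI	Intergenic	homopolymeric	AA	-	2	Insertion
atpA-atpF	Intergenic	homopolymeric	T	-	1	Insertion
atpF	Intron	homopolymeric	-	T	1	Deletion
ndhI-ndhA	Intergenic	homopolymeric	-	A	1	Deletion
ndhJ-ndhK	Intergenic	homopolymeric	-	T	1	Deletion
psbI-trnS	Intergenic	homopolymeric	-	T	1	Deletion
psbI-trnS	Intergenic	homopolymeric	-	A	1	Deletion
rbcL-accD	Intergenic	homopolymeric	-	A	1	Deletion
rps18-rpl20	Intergenic	homopolymeric	T	-	1	Insertion
trnE-trnT	Intergenic	homopolymeric	-	A	1	Deletion
trnK-rps16	Intergenic	homopolymeric	A	-	1	Insertion
trnK-rps16	Intergenic	homopolymeric	A	-	1	Insertion
trnL	Intron	homopolymeric	-	A	1	Deletion
trnL	Intron	homopolymeric	A	-	1	Insertion
trnL	Intron	homopolymeric	-	T	1	Deletion
trnR-aptA	Intergenic	homopolymeric	-	T	1	Deletion
atpH-atpI	Intergenic	non_homopolymeric	TTTATT	-	5	Insertion	printed_length_5_but_6_bases
clpP-psbB	Intergenic	non_homopolymeric	-	GTCTT	5	Deletion
petL-petG	Intergenic	non_homopolymeric	-	G	1	Deletion
rpoB-trnC	Intergenic	non_homopolymeric	-	TGTATT	5	Deletion	printed_length_5_but_6_bases
rpoB-trnC	Intergenic	non_homopolymeric	TACAA	-	5	Insertion
rrn23	Coding	non_homopolymeric	-	AATTAA	6	Deletion
rrn23	Coding	non_homopolymeric	-	TTAATT	6	Deletion
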