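no	location	motif	n_repeats	start	end	flags
1	trnK-matK	A	11	1658	1668
2	trnK-rps16	A	12	4210	4221
3	rps16-trnQ	A	10	6461	6470
4	trnQ-psbK	A	10	6957	6966
5	psbK-psbI	A	10	7578	7587
6	psbI-trnS	A	12	7854	7865
7	atpF intron	A	10	12476	12485
8	rpoC1 intron	A	10	22386	22395
9	trnE-trnT	A	10	31169	31178
10	trnL-intron	A	12	47464	47475
11	trnF-ndhJ	A	10	48982	48991
12	rbcL-accD	A	12	57323	57334
13	accD-psaI	A	10	59584	59593
14	psbF	A	10	64309	64318
15	clpP intron	A	10	71717	71726
16	petB intron	A	18	75505	75522
17	ndhI-ndhA	A	10	118705	118714
18	psaA	C	10	40165	40174
19	trnK-rps16	T	10	4464	4473
20	psbI-trnS	T	10	7745	7754
21	trnR-atpA	T	11	9948	9958
22	atpA-atpF	T	10	11532	11541
23	atpF intron	T	11	12457	12467
24	rps2-rpoC2	T	11	15957	15967
25	rps2-rpoC2	T	11	18156	18166
26	rpoB	T	10	25865	25874
27	trnD-trnY	T	10	30323	30332
28	trnL-trnF	T	10	48029	48038
29	ndhJ-ndhK	T	10	49646	49655
30	trnV intron	T	15	52214	52228
31	trnM-atpE	T	10	52658	52667
32	rbcL-accD	T	14	57377	57390
33	petL-petG	T	10	66141	66150
34	psaJ-rpl33	T	12	67499	67510
35	rps18-rpl20	T	10	68447	68456
36	rpoA	T	10	78219	78228
37	rps11-rpl36	T	12	79577	79588
38	rpl32-trnL	T	11	112371	112381	coordinate_typography_corrected
39	ndhA intron	T	12	119581	119592
40	ndhA intron	T	10	119793	119802
41	ycf1	T	12	125285	125296
42	ycf1	T	10	125890	125899
43	ycf1	T	14	126895	126908
44	ycf1	T	10	127195	127204
45	rps16-trnQ	AT	5	6277	6286
46	trnS-trnG	AT	5	8177	8186
47	trnS-trnG	AT	5	8300	8309
48	trnN-ndhF	TAA	4	109380	109391
49	psbA-trnK	TTGT	3	1522	1533
50	matK-trnK	TTCT	3	3873	3884
51	atpI-rps2	ATTA	3	15121	15132
52	trnE-trnY	ATTA	3	31084	31095
53	accD-psaI	TAAT	4	59721	59736
54	rps18-rpl20	TTTA	3	68474	68485
55	clpP intron	TTTC	3	71598	71609
56	rrn23	AGGT	3	104481	104492
57	trnL-ccsA	AACC	3	113312	113323
58	ycf1	TAAT	3	124297	124308
59	rrn23	CTAC	3	131310	131321	motif_typography_corrected
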