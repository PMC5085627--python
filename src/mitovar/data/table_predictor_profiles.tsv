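label	start	gene	ref	alt	aa_change	ci_percent	reported	ptc_count	thyroid_count	control_count	control_total	thyroid_total	polyphen2	sift	mutation_assessor	provean	snp_go	align_gvgd	panther
G3392A	3392	ND1	G	A	Gly->Asp	100.00	Y	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Disease	C65	NA
T3644C	3644	ND1	T	C	Val->Ala	97.60	Y	1	0	2	376	16	Benign	Not Tolerated	Medium	Deleterious	Neutral	C65	0.29125
T3679C	3679	ND1	T	C	Ser->Pro	100.00	Y	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Disease	C65	0.74261
G3745A	3745	ND1	G	A	Ala->Thr	92.70	Y	1	0	0	376	16	Benign	Not Tolerated	Low	Neutral	Neutral	C55	0.21113
G4971A	4971	ND2	G	A	Gly->Ser	100.00	N	1	0	0	376	16	Probably	Not Tolerated	Medium	Deleterious	Neutral	C55	0.36251
T6238C	6238	COI	T	C	Leu->Pro	100.00	N	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Disease	C65	0.87509
C6340T	6340	COI	C	T	Thr->Ile	82.90	Y	1	0	0	376	16	Benign	Not Tolerated	Medium	Neutral	Neutral	C65	0.21096
T6681C	6681	COI	T	C	Tyr->His	85.40	Y	1	0	0	376	16	Benign	Tolerated	Neutral	Neutral	Neutral	C65	0.32881
T7104C	7104	COI	T	C	Ser->Pro	100.00	N	1	0	0	376	16	Possibly	Not Tolerated	Neutral	Neutral	Disease	C65	0.5134
T7329C	7329	COI	T	C	Phe->Leu	100.00	N	1	0	0	376	16	Benign	Tolerated	Low	Neutral	Neutral	C15	0.16379
G8156A	8156	COII	G	A	Val->Met	75.61	N	1	0	0	376	16	Probably	Not Tolerated	Medium	Neutral	Neutral	C15	0.53442
G8989A	8989	ATP6	G	A	Ala->Thr	100.00	Y	1	0	0	376	16	Probably	Not Tolerated	Low	Deleterious	Neutral	C55	0.47286
T9187C	9187	ATP6	T	C	Tyr->His	100.00	Y	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Disease	C65	NA
A9355G	9355	COIII	A	G	Asn->Ser	82.90	Y	1	0	0	376	16	Benign	Tolerated	Neutral	Neutral	Neutral	C45	0.14014
G10573A	10573	ND4L	G	A	Gly->Glu	97.60	Y	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Neutral	C65	0.40946
A12850G	12850	ND5	A	G	Ile->Val	90.20	Y	1	0	0	376	16	Possibly	Tolerated	Neutral	Neutral	Neutral	C25	0.50297
A13535G	13535	ND5	A	G	Asn->Ser	87.80	Y	1	0	0	376	16	Benign	Not Tolerated	Low	Deleterious	Neutral	C45	NA
A13748G	13748	ND5	A	G	Asn->Ser	85.40	Y	1	0	0	376	16	Benign	Tolerated	Neutral	Neutral	Neutral	C45	0.5082
C14310A	14310	ND6	C	A	Gly->Trp	78.05	N	1	0	0	376	16	Probably	Not Tolerated	Medium	Deleterious	Disease	C65	0.71527
T14463C	14463	ND6	T	C	Thr->Ala	90.20	Y	1	0	0	376	16	Benign	Tolerated	Neutral	Deleterious	Neutral	C55	0.15283
T15018A	15018	Cytb	T	A	Phe->Tyr	100.00	N	1	0	0	376	16	Possibly	Not Tolerated	High	Deleterious	Disease	C15	0.68543
G15045A	15045	Cytb	G	A	Arg->Gln	100.00	Y	1	0	0	376	16	Probably	Not Tolerated	High	Deleterious	Disease	C35	0.59378
T15090C	15090	Cytb	T	C	Ile->Thr	85.40	Y	1	0	1	376	16	Possibly	Tolerated	Low	Deleterious	Neutral	C65	0.42865
T15479C	15479	Cytb	T	C	Phe->Leu	80.50	Y	1	0	0	376	16	Benign	Tolerated	Low	Deleterious	Neutral	C15	0.39962
C15483T	15483	Cytb	C	T	Ser->Leu	80.50	Y	1	0	0	376	16	Possibly	Tolerated	Low	Deleterious	Neutral	C65	0.45816
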