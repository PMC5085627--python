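label	start	end	gene	kind	ref	alt	reported	ptc_count	thyroid_count	control_count	zygosity
G4969A	4969	4969	ND2	substitution	G	A	N	1	0	0	homoplasmic
G5977A	5977	5977	COI	substitution	G	A	N	1	0	0	heteroplasmic
G7928A	7928	7928	COII	substitution	G	A	N	1	0	0	homoplasmic
G9253A	9253	9253	COIII	substitution	G	A	N	1	0	0	heteroplasmic
G10521A	10521	10521	ND4L	substitution	G	A	N	1	0	0	homoplasmic
T12794A	12794	12794	ND5	substitution	T	A	N	1	0	0	heteroplasmic
G13825A	13825	13825	ND5	substitution	G	A	N	1	0	0	homoplasmic
4520-4521delAC	4520	4521	ND2	deletion	AC		N	1	0	0	homoplasmic
10952insC	10952	10952	ND4	insertion		C	Y	1	0	0	homoplasmic
11032-11038 A7-6	11038	11038	ND4	deletion	A		Y	4	0	0	mixed
11646insT	11646	11646	ND4	insertion		T	N	1	0	0	homoplasmic
11673-11677 C5-4	11677	11677	ND4	deletion	C		N	1	0	0	heteroplasmic
11673-11677 C5-6	11677	11677	ND4	insertion		C	N	1	0	0	homoplasmic
12418-12425 A8-7	12425	12425	ND5	deletion	A		Y	1	0	0	heteroplasmic
12858insT	12858	12858	ND5	insertion		T	N	1	0	0	heteroplasmic
13128-13132 C5-4	13132	13132	ND5	deletion	C		N	1	0	0	homoplasmic
13170delA	13170	13170	ND5	deletion	A		N	1	0	0	homoplasmic
14495-14502 (AAAT)2-1	14499	14502	ND6	deletion	AAAT		N	1	0	0	homoplasmic
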