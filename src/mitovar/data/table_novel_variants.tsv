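label	start	end	gene	region	kind	ref	alt	ci_percent	ptc_count	control_count	zygosity
A1629T	1629	1629	tRNA-Val	rna	substitution	A	T	24.4	1	0	homoplasmic
A2274G	2274	2274	16S rRNA	rna	substitution	A	G	100	1	0	heteroplasmic
3275-3276delCA	3275	3276	tRNA-Leu(UUR)	rna	deletion	CA		-	1	0	heteroplasmic
T4272C	4272	4272	tRNA-Ile	rna	substitution	T	C	100	1	0	homoplasmic
5835insT	5835	5835	tRNA-Tyr	rna	insertion		T	-	1	0	homoplasmic
G5881C	5881	5881	tRNA-Tyr	rna	substitution	G	C	100	1	0	homoplasmic
C10040A	10040	10040	tRNA-Gly	rna	substitution	C	A	43.9	1	0	homoplasmic
4520-4521delAC	4520	4521	ND2	protein	deletion	AC		-	1	0	homoplasmic
C4875T	4875	4875	ND2	protein	substitution	C	T	100	1	0	homoplasmic
G4969A	4969	4969	ND2	protein	substitution	G	A	100	1	0	homoplasmic
G4971A	4971	4971	ND2	protein	substitution	G	A	100	1	0	homoplasmic
G5977A	5977	5977	COI	protein	substitution	G	A	100	1	0	heteroplasmic
T6238C	6238	6238	COI	protein	substitution	T	C	100	1	0	heteroplasmic
T7104C	7104	7104	COI	protein	substitution	T	C	100	1	0	heteroplasmic
C7750A	7750	7750	COII	protein	substitution	C	A	58.5	1	0	homoplasmic
G7928A	7928	7928	COII	protein	substitution	G	A	56.1	1	0	homoplasmic
G9253A	9253	9253	COIII	protein	substitution	G	A	100	1	0	heteroplasmic
G10521A	10521	10521	ND4L	protein	substitution	G	A	100	1	0	homoplasmic
C10622T	10622	10622	ND4L	protein	substitution	C	T	36.6	1	0	homoplasmic
11646insT	11646	11646	ND4	protein	insertion		T	-	1	0	homoplasmic
11673-11677 C5-4	11677	11677	ND4	protein	deletion	C		-	1	0	heteroplasmic
11673-11677 C5-6	11677	11677	ND4	protein	insertion		C	-	1	0	homoplasmic
T12794A	12794	12794	ND5	protein	substitution	T	A	100	1	0	heteroplasmic
12858insT	12858	12858	ND5	protein	insertion		T	-	1	0	heteroplasmic
C12943T	12943	12943	ND5	protein	substitution	C	T	24.4	1	0	heteroplasmic
13128-13132 C5-4	13132	13132	ND5	protein	deletion	C		-	1	0	homoplasmic
13170delA	13170	13170	ND5	protein	deletion	A		-	1	0	homoplasmic
C13621T	13621	13621	ND5	protein	substitution	C	T	51.2	1	0	homoplasmic
G13825A	13825	13825	ND5	protein	substitution	G	A	100	1	0	homoplasmic
C14310A	14310	14310	ND6	protein	substitution	C	A	70.7	1	0	heteroplasmic
14495-14502 (AAAT)2-1	14499	14502	ND6	protein	deletion	AAAT		-	1	0	homoplasmic
C14774A	14774	14774	Cytb	protein	substitution	C	A	63.4	1	0	heteroplasmic
T15018A	15018	15018	Cytb	protein	substitution	T	A	100	1	0	heteroplasmic
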