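label	gene	note
A3243G	tRNA-Leu(UUR)	MELAS hotspot
G3244A	tRNA-Leu(UUR)	reported in mitochondrial myopathy and oncocytic thyroid tumors
A5514G	tRNA-Trp	neonatal-onset mitochondrial disease
T5628C	tRNA-Ala	anticodon-stem destabilizing
A8344G	tRNA-Lys	MERRF hotspot
10952insC	ND4	renal oncocytoma
11032-11038 A7-6	ND4	renal oncocytoma; prostate cancer
12418-12425 A8-7	ND5	chronic renal failure with lactic acidosis; cancers
G3392A	ND1	disease-associated
T3644C	ND1	disease-associated
T3679C	ND1	disease-associated
G3745A	ND1	disease-associated
C6340T	COI	disease-associated
T6681C	COI	disease-associated
G8989A	ATP6	disease-associated
T9187C	ATP6	disease-associated
A9355G	COIII	disease-associated
G10573A	ND4L	disease-associated
A12850G	ND5	disease-associated
A13535G	ND5	disease-associated
A13748G	ND5	disease-associated
T14463C	ND6	disease-associated
G15045A	Cytb	disease-associated
T15090C	Cytb	disease-associated
T15479C	Cytb	disease-associated
C15483T	Cytb	disease-associated
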