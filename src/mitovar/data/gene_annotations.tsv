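name	start	end	strand	kind
D-loop	16024	576	H	control-region
tRNA-Phe	577	647	H	tRNA
12S rRNA	648	1601	H	rRNA
tRNA-Val	1602	1670	H	tRNA
16S rRNA	1671	3229	H	rRNA
tRNA-Leu(UUR)	3230	3304	H	tRNA
ND1	3307	4262	H	protein
tRNA-Ile	4263	4331	H	tRNA
tRNA-Gln	4329	4400	L	tRNA
tRNA-Met	4402	4469	H	tRNA
ND2	4470	5511	H	protein
tRNA-Trp	5512	5579	H	tRNA
tRNA-Ala	5587	5655	L	tRNA
tRNA-Asn	5657	5729	L	tRNA
tRNA-Cys	5761	5826	L	tRNA
tRNA-Tyr	5826	5891	L	tRNA
COI	5904	7445	H	protein
tRNA-Ser(UCN)	7446	7514	L	tRNA
tRNA-Asp	7518	7585	H	tRNA
COII	7586	8269	H	protein
tRNA-Lys	8295	8364	H	tRNA
ATP8	8366	8572	H	protein
ATP6	8527	9207	H	protein
COIII	9207	9990	H	protein
tRNA-Gly	9991	10058	H	tRNA
ND3	10059	10404	H	protein
tRNA-Arg	10405	10469	H	tRNA
ND4L	10470	10766	H	protein
ND4	10760	12137	H	protein
tRNA-His	12138	12206	H	tRNA
tRNA-Ser(AGY)	12207	12265	H	tRNA
tRNA-Leu(CUN)	12266	12336	H	tRNA
ND5	12337	14148	H	protein
ND6	14149	14673	L	protein
tRNA-Glu	14674	14742	L	tRNA
Cytb	14747	15887	H	protein
tRNA-Thr	15888	15953	H	tRNA
tRNA-Pro	15956	16023	L	tRNA
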