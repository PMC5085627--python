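node	parent	defining_variants
mt-MRCA
L3	mt-MRCA	A73G,C150T
M	L3	T489C,A10398G
N	L3	C195T,A663G
C	M	A1736G,T2706C
D	M	C2092T,T16092C
G	M	T1888C,A16227G
Z	M	T152C,C16260T
A	N	A235G,C16290T
A4	A	G16319A
B4	N	T16217C
B4a	B4	C16261T
B4g	B4	T16140C
F	N	T16304C
R	N	T16126C
Y	N	A16231G
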