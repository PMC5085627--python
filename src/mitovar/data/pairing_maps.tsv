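gene	pos1	pos2
tRNA-Val	1629	1652
tRNA-Ile	4272	4300
tRNA-Tyr	5881	5860
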