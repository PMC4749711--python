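name	sequence	role	assay	annealing_temp_c
Sphingo108f	GCGTAACGCGTGGGAATCTG	forward	16S_rDNA_PCR	62
Sphingo420r	TTACAACCCTAAGGCCTTC	reverse	16S_rDNA_PCR	62
16S-1511f	AAGTCGTAACAAGGTARCCG	forward	16S-23S_ITS_PCR	60
23S-23r	YYGCCAAGGCATCCACC	reverse	16S-23S_ITS_PCR	60
1492f	AAGTCGTAACAAGGTAACC	forward	16S-23S_ITS_PCR	60
115r	GGGTTBCCCCATTCRG	reverse	16S-23S_ITS_PCR	60
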