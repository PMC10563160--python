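name	mass	residues	nterm_only
Oxidation	15.99491	MWHFYC	0
Methylation	14.01565	KRC	0
Dimethylation	28.03130	KR	0
Trimethylation	42.04695	KR	0
Acetylation	42.01057	K	0
N-terminal acetylation	42.01057	-	1
Phosphorylation	79.96633	STY	0
Carbamylation	43.00581	KRCM	0
Carbamidomethylation	57.02146	C	0
Sodium adduct	21.98194	DE	0
Potassium adduct	37.95588	DE	0
Deamidation	0.98402	NQ	0
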