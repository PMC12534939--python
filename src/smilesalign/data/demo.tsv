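# Mixed small-molecule demo set covering C/O/N/S chemistry, aromatics
# and branching; used to diversify the scoring corpus in tests.
order	id	smiles
0	ethanol	CCO
1	acetic_acid	CC(=O)O
2	acetone	CC(C)=O
3	benzene	c1ccccc1
4	phenol	Oc1ccccc1
5	pyridine	c1ccncc1
6	glycine	NCC(=O)O
7	urea	NC(N)=O
8	lactic_acid	CC(O)C(=O)O
9	dimethyl_sulfide	CSC
10	ethylamine	CCN
11	glycerol	OCC(O)CO
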