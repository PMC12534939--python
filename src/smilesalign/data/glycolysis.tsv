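# Glycolysis, glucose through pyruvate, main-chain metabolites only
# (coenzymes excluded; DHAP omitted in favour of the G3P branch).
# Sugars are written in their open-chain forms; neutral acids/phosphates.
# Reconstructed textbook structures for testing.
order	id	smiles
0	glucose	OCC(O)C(O)C(O)C(O)C=O
1	glucose_6_phosphate	O=CC(O)C(O)C(O)C(O)COP(=O)(O)O
2	fructose_6_phosphate	OCC(=O)C(O)C(O)C(O)COP(=O)(O)O
3	fructose_16_bisphosphate	OP(=O)(O)OCC(=O)C(O)C(O)C(O)COP(=O)(O)O
4	glyceraldehyde_3_phosphate	O=CC(O)COP(=O)(O)O
5	13_bisphosphoglycerate	O=C(OP(=O)(O)O)C(O)COP(=O)(O)O
6	3_phosphoglycerate	OC(=O)C(O)COP(=O)(O)O
7	2_phosphoglycerate	OC(=O)C(OP(=O)(O)O)CO
8	phosphoenolpyruvate	OC(=O)C(=C)OP(=O)(O)O
9	pyruvate	CC(=O)C(=O)O
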