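# Pentose phosphate pathway treated as a cycle: oxidative phase from
# glucose-6-phosphate, then the non-oxidative sugar shuffle returning to
# fructose-6-phosphate, which isomerizes back to the start. Open-chain
# sugar forms, neutral phosphates. Reconstructed textbook structures.
order	id	smiles
0	glucose_6_phosphate	O=CC(O)C(O)C(O)C(O)COP(=O)(O)O
1	6_phosphogluconolactone	O=C1OC(COP(=O)(O)O)C(O)C(O)C1O
2	6_phosphogluconate	OC(=O)C(O)C(O)C(O)C(O)COP(=O)(O)O
3	ribulose_5_phosphate	OCC(=O)C(O)C(O)COP(=O)(O)O
4	ribose_5_phosphate	O=CC(O)C(O)C(O)COP(=O)(O)O
5	sedoheptulose_7_phosphate	OCC(=O)C(O)C(O)C(O)C(O)COP(=O)(O)O
6	erythrose_4_phosphate	O=CC(O)C(O)COP(=O)(O)O
7	fructose_6_phosphate	OCC(=O)C(O)C(O)C(O)COP(=O)(O)O
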