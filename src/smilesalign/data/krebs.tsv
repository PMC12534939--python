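# Krebs cycle (citric acid cycle), seven primary metabolites in pathway
# order, coenzymes and CoA-bound intermediates excluded. Structures are
# standard textbook neutral acids, reconstructed for testing; not copied
# from any external corpus.
order	id	smiles
0	oxaloacetate	OC(=O)CC(=O)C(=O)O
1	citrate	OC(=O)CC(O)(CC(=O)O)C(=O)O
2	isocitrate	OC(=O)C(C(O)C(=O)O)CC(=O)O
3	alpha_ketoglutarate	OC(=O)CCC(=O)C(=O)O
4	succinate	OC(=O)CCC(=O)O
5	fumarate	OC(=O)C=CC(=O)O
6	malate	OC(=O)CC(O)C(=O)O
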