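# SYNTHETIC reconstruction: truth alignments generated with smilesalign.validation.truth_from_mcs (RDKit FindMCS atom map, monotone LIS projection onto canonical token order), standing in for manually curated biochemical correspondence. v1
pair_id	gapped_a	gapped_b
oxaloacetate|citrate	OCOCCO-----COO	OCOCC-OCCOOCOO
oxaloacetate|isocitrate	OCOCCOCOO-----	OCOCC-COOCOCOO
oxaloacetate|alpha_ketoglutarate	OCOCCOCOO---	OCOCC-CO-COO
oxaloacetate|succinate	OCOCCOCOO	OCOCC-COO
oxaloacetate|fumarate	OCOCCOCOO----	OCOC-----CCOO
oxaloacetate|malate	OCOCCO-COO	OCOCC-OCOO
citrate|isocitrate	OCOCCO---C-COOCOO	OCOCC-COOCOCOO---
citrate|alpha_ketoglutarate	OCOCCOC-COOCOO	OCOCC-COCOO---
citrate|succinate	OCOCCOCCOOCOO	OCOCC-----COO
citrate|fumarate	OCOCCOCCOOCOO----	OCOC---------CCOO
citrate|malate	OCOCCOCCOOCOO	OCOCCO----COO
isocitrate|alpha_ketoglutarate	OCOCCCOOCO-COO	OCOCC---C-OCOO
isocitrate|succinate	OCOCCCOOCOCOO	OCOCCCOO-----
isocitrate|fumarate	OCOCCCOOCOCOO----	OCOC---------CCOO
isocitrate|malate	OCOCC-COO-COCOO	-----OC-OCCOCOO
alpha_ketoglutarate|succinate	OCOCCCOCOO-	OCOCCCO---O
alpha_ketoglutarate|fumarate	OCOCCCOCOO----	OCOC------CCOO
alpha_ketoglutarate|malate	OCOCC-COCOO-	OCOCCOCO---O
succinate|fumarate	OCOCCCOO----	OCOC----CCOO
succinate|malate	OCOCC-COO	OCOCCOCOO
fumarate|malate	OCOCCCOO-----	OCOC----COCOO
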