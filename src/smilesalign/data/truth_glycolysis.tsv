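# SYNTHETIC reconstruction: truth alignments generated with smilesalign.validation.truth_from_mcs (RDKit FindMCS atom map, monotone LIS projection onto canonical token order), standing in for manually curated biochemical correspondence. v1
pair_id	gapped_a	gapped_b
glucose|glucose_6_phosphate	OCCOCOCOCOCO----	OCCOCOCOCOCOPOOO
glucose|fructose_6_phosphate	OC--COCOCOCOCO----	OCCOCOCOCOCO--POOO
glucose|fructose_16_bisphosphate	OC------COCOCOCOCO----	OCCOPOOOCOCOCOCO--POOO
glucose|glyceraldehyde_3_phosphate	OCCOCOCOCOCO----	OCCOCO------POOO
glucose|13_bisphosphoglycerate	OC-----COCOCOCOCO----	OCOPOOOCOCO------POOO
glucose|3_phosphoglycerate	OC-COCOCOCOCO----	OCOCOCO------POOO
glucose|2_phosphoglycerate	OC-COCOCOCOCO-----	OCOC-CO------OPOOO
glucose|phosphoenolpyruvate	OC-COCOCOCOCO-------	--CCO--------POOOCOO
glucose|pyruvate	----OCCOCOCOCOCO-	CCOCO-----------O
glucose_6_phosphate|fructose_6_phosphate	O--CCO-COCOCOCOPOOO	-OCC--OCOCOCOCOPOOO
glucose_6_phosphate|fructose_16_bisphosphate	OCCOCOCO-COCOPOOO------------	--------OC-COPOOOCOCOCOCOPOOO
glucose_6_phosphate|glyceraldehyde_3_phosphate	OCCOCO-COCOCOPOOO	------OC-COCOPOOO
glucose_6_phosphate|13_bisphosphoglycerate	OCCOCOCOCO-COPOOO--------	----------OCOPOOOCOCOPOOO
glucose_6_phosphate|3_phosphoglycerate	OCCOCO-COCOCOPOOO	------OCOCOCOPOOO
glucose_6_phosphate|2_phosphoglycerate	OCCOCOCO-COC--OPOOO	--------OCOCCOOPOOO
glucose_6_phosphate|phosphoenolpyruvate	OCCOCOCOCO-COPOOO---	----------CCOPOOOCOO
glucose_6_phosphate|pyruvate	----OCCOCOCOCOCOPOOO-	CCOCO---------------O
fructose_6_phosphate|fructose_16_bisphosphate	OCCO----COCOCOCOPOOO	OCCOPOOOCOCOCOCOPOOO
fructose_6_phosphate|glyceraldehyde_3_phosphate	OCCOCO-COCOCOPOOO	------OC-COCOPOOO
fructose_6_phosphate|13_bisphosphoglycerate	OCCOCOCOCO-COPOOO--------	----------OCOPOOOCOCOPOOO
fructose_6_phosphate|3_phosphoglycerate	OCCOCO-COCOCOPOOO	------OCOCOCOPOOO
fructose_6_phosphate|2_phosphoglycerate	OCCOCOCO-COC--OPOOO	--------OCOCCOOPOOO
fructose_6_phosphate|phosphoenolpyruvate	OCCOCOCOCO-COPOOO---	----------CCOPOOOCOO
fructose_6_phosphate|pyruvate	--OCCOC-OCOCOCOPOOO	CCO---COO----------
fructose_16_bisphosphate|glyceraldehyde_3_phosphate	OCCOPOOOCO-COCOCOPOOO	----------OC-COCOPOOO
fructose_16_bisphosphate|13_bisphosphoglycerate	OCCOPOOOCOCOCO-COPOOO--------	--------------OCOPOOOCOCOPOOO
fructose_16_bisphosphate|3_phosphoglycerate	OCCOPOOOCO-COCOCOPOOO	----------OCOCOCOPOOO
fructose_16_bisphosphate|2_phosphoglycerate	OC-C--OPOOOCOCOCOCOPOOO	OCOCCOOPOOO------------
fructose_16_bisphosphate|phosphoenolpyruvate	OCCOPOOOCOCOCO-COPOOO---	--------------CCOPOOOCOO
fructose_16_bisphosphate|pyruvate	--OCCOPOOOC-OCOCOCOPOOO	CCO-------COO----------
glyceraldehyde_3_phosphate|13_bisphosphoglycerate	OC-----COCOPOOO	OCOPOOOCOCOPOOO
glyceraldehyde_3_phosphate|3_phosphoglycerate	OC-COCOPOOO	OCOCOCOPOOO
glyceraldehyde_3_phosphate|2_phosphoglycerate	OC-COC--OPOOO	--OCOCCOOPOOO
glyceraldehyde_3_phosphate|phosphoenolpyruvate	OCCO-COPOOO---	----CCOPOOOCOO
glyceraldehyde_3_phosphate|pyruvate	----OCCOCOPOOO-	CCOCO---------O
13_bisphosphoglycerate|3_phosphoglycerate	OCOPOOOCOCOPOOO	OCO----COCOPOOO
13_bisphosphoglycerate|2_phosphoglycerate	O---C--OPOOOCOCOPOOO	-OCOCCOOPOOO--------
13_bisphosphoglycerate|phosphoenolpyruvate	O-COPOOOC-OCOPOOO	-CCOPOOOCOO------
13_bisphosphoglycerate|pyruvate	----OCOPOOOCOCOPOOO	CCOCO-O------------
3_phosphoglycerate|2_phosphoglycerate	OCO-COC--OPOOO	---OCOCCOOPOOO
3_phosphoglycerate|phosphoenolpyruvate	OCOCO-COPOOO---	-----CCOPOOOCOO
3_phosphoglycerate|pyruvate	----OCOCOCOPOOO	CCOCO-O--------
2_phosphoglycerate|phosphoenolpyruvate	OCO-CCOOPOOO---	---CC--OPOOOCOO
2_phosphoglycerate|pyruvate	----OCOCCOOPOOO	CCOCO-O--------
phosphoenolpyruvate|pyruvate	C---C-OPOOOCOO	-CCOCOO-------
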