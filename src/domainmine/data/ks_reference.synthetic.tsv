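domain_id	domain_type	class_label	pathway_name	pathway_type	product	gene_accession	literature_ref
Enediyne_1	KS	Enediyne	Enediyne synthetic pathway 1	PKS	calicheamicin	SYNKS0000	synthetic
Enediyne_2	KS	Enediyne	Enediyne synthetic pathway 2	PKS	calicheamicin	SYNKS0001	synthetic
Enediyne_3	KS	Enediyne	Enediyne synthetic pathway 3	PKS	calicheamicin	SYNKS0002	synthetic
TransAT_1	KS	Trans-AT	Trans-AT synthetic pathway 1	PKS	leinamycin	SYNKS0100	synthetic
TransAT_2	KS	Trans-AT	Trans-AT synthetic pathway 2	PKS	leinamycin	SYNKS0101	synthetic
TransAT_3	KS	Trans-AT	Trans-AT synthetic pathway 3	PKS	leinamycin	SYNKS0102	synthetic
CisAT_1	KS	Cis-AT	Cis-AT synthetic pathway 1	PKS	erythromycin	SYNKS0200	synthetic
CisAT_2	KS	Cis-AT	Cis-AT synthetic pathway 2	PKS	erythromycin	SYNKS0201	synthetic
CisAT_3	KS	Cis-AT	Cis-AT synthetic pathway 3	PKS	erythromycin	SYNKS0202	synthetic
Hybrid_1	KS	Hybrid	Hybrid synthetic pathway 1	hybrid	microcystin	SYNKS0300	synthetic
Hybrid_2	KS	Hybrid	Hybrid synthetic pathway 2	hybrid	microcystin	SYNKS0301	synthetic
Hybrid_3	KS	Hybrid	Hybrid synthetic pathway 3	hybrid	microcystin	SYNKS0302	synthetic
Iterative_1	KS	Iterative	Iterative synthetic pathway 1	PKS	aflatoxin	SYNKS0400	synthetic
Iterative_2	KS	Iterative	Iterative synthetic pathway 2	PKS	aflatoxin	SYNKS0401	synthetic
Iterative_3	KS	Iterative	Iterative synthetic pathway 3	PKS	aflatoxin	SYNKS0402	synthetic
PUFA_1	KS	PUFA	PUFA synthetic pathway 1	PKS	omega-3 fatty acid	SYNKS0500	synthetic
PUFA_2	KS	PUFA	PUFA synthetic pathway 2	PKS	omega-3 fatty acid	SYNKS0501	synthetic
PUFA_3	KS	PUFA	PUFA synthetic pathway 3	PKS	omega-3 fatty acid	SYNKS0502	synthetic
KS1_1	KS	KS1	KS1 synthetic pathway 1	PKS	salinosporamide	SYNKS0600	synthetic
KS1_2	KS	KS1	KS1 synthetic pathway 2	PKS	salinosporamide	SYNKS0601	synthetic
KS1_3	KS	KS1	KS1 synthetic pathway 3	PKS	salinosporamide	SYNKS0602	synthetic
TypeII_1	KS	Type II	Type II synthetic pathway 1	PKS	actinorhodin	SYNKS0700	synthetic
TypeII_2	KS	Type II	Type II synthetic pathway 2	PKS	actinorhodin	SYNKS0701	synthetic
TypeII_3	KS	Type II	Type II synthetic pathway 3	PKS	actinorhodin	SYNKS0702	synthetic
FAS_1	KS	FAS	FAS synthetic pathway 1	FAS	palmitic acid	SYNKS0800	synthetic
FAS_2	KS	FAS	FAS synthetic pathway 2	FAS	palmitic acid	SYNKS0801	synthetic
FAS_3	KS	FAS	FAS synthetic pathway 3	FAS	palmitic acid	SYNKS0802	synthetic
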