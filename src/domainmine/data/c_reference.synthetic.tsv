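domain_id	domain_type	class_label	pathway_name	pathway_type	product	gene_accession	literature_ref
LCL_1	C	LCL	LCL synthetic pathway 1	NRPS	surfactin	SYNC0000	synthetic
LCL_2	C	LCL	LCL synthetic pathway 2	NRPS	surfactin	SYNC0001	synthetic
LCL_3	C	LCL	LCL synthetic pathway 3	NRPS	surfactin	SYNC0002	synthetic
DCL_1	C	DCL	DCL synthetic pathway 1	NRPS	tyrocidine	SYNC0100	synthetic
DCL_2	C	DCL	DCL synthetic pathway 2	NRPS	tyrocidine	SYNC0101	synthetic
DCL_3	C	DCL	DCL synthetic pathway 3	NRPS	tyrocidine	SYNC0102	synthetic
Starter_1	C	Starter	Starter synthetic pathway 1	NRPS	surfactin lipoinitiation	SYNC0200	synthetic
Starter_2	C	Starter	Starter synthetic pathway 2	NRPS	surfactin lipoinitiation	SYNC0201	synthetic
Starter_3	C	Starter	Starter synthetic pathway 3	NRPS	surfactin lipoinitiation	SYNC0202	synthetic
Cyclization_1	C	Cyclization	Cyclization synthetic pathway 1	NRPS	bacitracin	SYNC0300	synthetic
Cyclization_2	C	Cyclization	Cyclization synthetic pathway 2	NRPS	bacitracin	SYNC0301	synthetic
Cyclization_3	C	Cyclization	Cyclization synthetic pathway 3	NRPS	bacitracin	SYNC0302	synthetic
Epimerization_1	C	Epimerization	Epimerization synthetic pathway 1	NRPS	gramicidin	SYNC0400	synthetic
Epimerization_2	C	Epimerization	Epimerization synthetic pathway 2	NRPS	gramicidin	SYNC0401	synthetic
Epimerization_3	C	Epimerization	Epimerization synthetic pathway 3	NRPS	gramicidin	SYNC0402	synthetic
DualEC_1	C	Dual E/C	Dual E/C synthetic pathway 1	NRPS	arthrofactin	SYNC0500	synthetic
DualEC_2	C	Dual E/C	Dual E/C synthetic pathway 2	NRPS	arthrofactin	SYNC0501	synthetic
DualEC_3	C	Dual E/C	Dual E/C synthetic pathway 3	NRPS	arthrofactin	SYNC0502	synthetic
ModifiedAA_1	C	Modified AA	Modified AA synthetic pathway 1	NRPS	bleomycin	SYNC0600	synthetic
ModifiedAA_2	C	Modified AA	Modified AA synthetic pathway 2	NRPS	bleomycin	SYNC0601	synthetic
ModifiedAA_3	C	Modified AA	Modified AA synthetic pathway 3	NRPS	bleomycin	SYNC0602	synthetic
HybridC_1	C	Hybrid C	Hybrid C synthetic pathway 1	hybrid	mycosubtilin	SYNC0700	synthetic
HybridC_2	C	Hybrid C	Hybrid C synthetic pathway 2	hybrid	mycosubtilin	SYNC0701	synthetic
HybridC_3	C	Hybrid C	Hybrid C synthetic pathway 3	hybrid	mycosubtilin	SYNC0702	synthetic
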