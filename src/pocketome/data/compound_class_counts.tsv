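class_name	chebi_roots	n_found	n_not_found
Nucleobases, nucleosides & nucleotides	CHEBI:18282,CHEBI:33838,CHEBI:36976	8092	2244
Inorganic ions	CHEBI:36914	1191	7265
Other compounds		1114	296
Carbohydrates & derivatives	CHEBI:16646,CHEBI:63299	548	103
Amino acids & derivatives	CHEBI:33709,CHEBI:35238,CHEBI:83821	260	135
Lipids	CHEBI:18059	173	94
Hetero nuclear clusters	CHEBI:33733	84	433
Oligo- & polypeptides	CHEBI:25676,CHEBI:15841	79	92
Monosaccharides & derivatives	CHEBI:35381,CHEBI:63367	71	34
Glycans	CHEBI:37163,CHEBI:167559	73	4
Hemes	CHEBI:30413	13	2
Nucleic acids	CHEBI:16991,CHEBI:33697	0	7
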