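species	kingdom	n_pred_structures	n_known_pockets	n_known_pockets_exp	n_pred_pockets
ECOLI	Bacteria	3813	1014	224	2648
YEAST	Fungi	5623	1207	109	3000
CANAL	Fungi	5622	400	11	3124
ARATH	Plantae	24778	4668	169	11075
ORYSJ	Plantae	30708	1925	25	10618
MAIZE	Plantae	35165	681	9	13177
SOYBN	Plantae	47539	1220	0	20915
DROME	Animalia	12389	1110	19	5867
CAEEL	Animalia	17819	1091	10	8850
MOUSE	Animalia	20367	4439	146	10133
HUMAN	Animalia	19268	4451	975	8108
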