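species	n_communities	n_singletons	largest_community
ECOLI	273	1076	185
YEAST	335	1182	133
CANAL	300	1293	124
ARATH	823	1532	893
ORYSJ	780	1711	924
MAIZE	966	1879	1086
SOYBN	1376	1792	1868
DROME	514	1688	328
CAEEL	617	2225	406
MOUSE	708	1805	1068
HUMAN	682	1705	516
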