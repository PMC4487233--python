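symbol	name	gene_id	chromosome
AMBP	alpha-1-microglobulin/bikunin precursor	259	9q32-q33
APOD	apolipoprotein D	347	3q29
APOM	apolipoprotein M	55937	6p21.33
C8G	complement component 8, gamma polypeptide	733	9q34.3
CRABP1	cellular retinoic acid binding protein 1	1381	15q24
CRABP2	cellular retinoic acid binding protein 2	1382	1q21.3
FABP1	fatty acid binding protein 1, liver	2168	2p11
FABP12	fatty acid binding protein 12	646486	8q21.13
FABP2	fatty acid binding protein 2, intestinal	2169	4q28-q31
FABP3	fatty acid binding protein 3, muscle and heart (mammary-derived growth inhibitor)	2170	1p33-p32
FABP4	fatty acid binding protein 4, adipocyte	2167	8q21
FABP5	fatty acid binding protein 5 (psoriasis-associated)	2171	8q21.13
FABP6	fatty acid binding protein 6, ileal	2172	5q33.3-q34
FABP7	fatty acid binding protein 7, brain	2173	6q22-q23
FABP9	fatty acid binding protein 9, testis	646480	8q21.13
LCN1	lipocalin 1	3933	9q34
LCN10	lipocalin 10	414332	9q34.3
LCN12	lipocalin 12	286256	9q34.3
LCN15	lipocalin 15	389812	9q34.3
LCN1P1	lipocalin 1 pseudogene 1	286310	9q34.2
LCN2	lipocalin 2	3934	9q34
LCN6	lipocalin 6	158062	9q34.3
LCN8	lipocalin 8	138307	9q34.3
LCN9	lipocalin 9	392399	9q34.3
LCNL1	lipocalin-like 1	401562	9q34.3
OBP2A	odorant binding protein 2A	29991	9q34
OBP2B	odorant binding protein 2B	29989	9q34
ORM1	orosomucoid 1	5004	9q32
ORM2	orosomucoid 2	5005	9q32
PAEP	progestagen-associated endometrial protein	5047	9q34
PMP2	peripheral myelin protein 2	5375	8q21.3-q22.1
PTGDS	prostaglandin D2 synthase 21kDa (brain)	5730	9q34.2-q34.3
RBP1	retinol binding protein 1, cellular	5947	3q23
RBP2	retinol binding protein 2, cellular	5948	3q23
RBP4	retinol binding protein 4, plasma	5950	10q23.33
RBP5	retinol binding protein 5, cellular	83758	12p13.31
RBP7	retinol binding protein 7, cellular	116362	1p36.22
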