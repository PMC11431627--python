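country	plasmid	size_bp	gc_percent	accession
Argentina	pCOLO-c1	5857	53.9	BK067852
Australia	pL6A	6129	51.0	FR746101
Australia	pL6B	6056	52.0	FR746102
Australia	pBAJ9-6	6213	53.0	LT984491
Australia	pLT53-7	7045	51.0	LT984489
Australia	pLTMV-6	5884	53.0	LT991975
Australia	pHILL-c1	6187	52.4	BK067853
Australia	pHILL-c2	7625	51.5	BK067854
Australia	pTYRR-r1	5844	51.0	BK067859
Puerto Rico	pCABO-c1	5007	48.4	BK067804
Puerto Rico	pCABO-c2	5889	53.7	BK067846
Puerto Rico	pCABO-c6	5864	53.0	BK067847
Puerto Rico	pCABO-c9	6930	49.3	BK067848
Puerto Rico	pCABO-c10	5219	51.4	BK067849
Puerto Rico	pCABO-s1	6206	47.8	BK067850
Puerto Rico	pCABO-s5	5017	58.5	BK067851
Spain	pISLA-c6	5881	53.6	BK067855
Spain	pISLA-s1	5606	64.0	BK067856
Spain	pMALL-c2	5504	52.6	BK067857
Spain	pPOLA-c1	6075	48.1	BK067858
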