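plasmid	variant	F1	F2	F3	R4	R5	R6	R7
pL6A	canonical	F1	F2	F3	R4	R5	R6	R7
pL6B	canonical	F1	F2	F3	R4	R5	R6	R7
pLTMV-6	canonical	F1	F2	F3	R4	R5	R6	R7
pLT53-7	canonical	F1	F2	F3	R4	R5	R6/ps.	R7
pBAJ9-6	canonical	F1	F2	F3	R4	R5	R6	R7
pCABO-c6	canonical	F1	F2	F3	R4	R5	R6	R7
pCABO-c2	canonical	F1	F2	F3	R4	R5	R6	R7
pCABO-c9	canonical	F1	F2	F3	R4	R5	R6	-
pHILL-c2	canonical	F1	F2	F3	R4	R5	R6	R7
pCOLO-c2	canonical	F1	F2	F3	R4	R5	R6	R7
pISLA-c6	canonical	F1	F2	F3	R4	R5	R6	R7
pHILL-c1	canonical	F1	F2	F3	R4	R5	R6	R7
pTYRR-r1	no_F2	F1	-	F3	R4	R5	R6	R7
pCABO-c1	no_F2	F1	-	F3	R4	R5	R6	-
pCABO-c10	no_F2	F1	-	F3	R4	R5	R6	-
pMALL-c2	F2b/F2a	F1	F2b/F2a	F3	R4	R5	R6	R7
pPOLA-c1	F2b/F2a	F1	F2b/F2a	F3	R4	R5	R6	-
pCABO-s1	F2b/F2a	F1	F2b/F2a	F3	-	R5	R6	-
pISLA-s1	F1b/F2a/F2c	F1b	F2a/F2c	F3	R4	R5	R6	R7
pCABO-s5	F1b/F2a/F2c	F1b	F2a/F2c	F3	R4	R5	R6	-
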