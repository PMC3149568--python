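probeset_id	gene_symbol	entrez_id	frequency
221728_x_at	XIST	7503	100
221729_at	COL5A2	1290	100
221730_at	COL5A2	1290	100
206552_s_at	TAC1	6863	90
200800_s_at	HSPA1A	3303	60
200664_s_at	DNAJB1	3337	50
201645_at	TNC	3371	50
204337_at	RGS4	5999	50
212063_at	CD44	960	50
213436_at	CNR1	1268	50
202018_s_at	LTF	4057	40
220122_at	MCTP1	79772	40
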