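probeset_id	gene_symbol	entrez_id	frequency
202234_s_at	SLC16A1	6566	100
205048_s_at	PSPH	5723	100
212063_at	CD44	960	100
213921_at	SST	6750	100
223380_s_at	LATS2	26524	100
230629_s_at	EP400	57634	100
231735_s_at	MALAT1	378938	100
235987_at	PRKXP1	441733	100
204142_at	ENOSF1	55556	80
212417_at	SCAMP1	9522	80
213872_at	C6orf62	81688	80
214246_x_at	MINK1	50488	80
217028_at	CXCR4	7852	80
220122_at	MCTP1	79772	80
220182_at	SLC25A23	79085	80
221646_s_at	ZDHHC11	79844	80
227413_at	UBLCP1	134510	80
228697_at	HINT3	135114	80
209116_x_at	HBB	3043	60
212451_at	SECISBP2L	9728	60
216834_at	RGS1	5996	60
224588_at	XIST	7503	60
228946_at	INTU	27152	60
229120_s_at	CDC42SE1	56882	60
230748_at	SLC16A6	9120	60
1554447_at	LOC554203	554203	60
1569110_x_at	LOC728613	728613	60
202436_s_at	CYP1B1	1545	40
203540_at	GFAP	2670	40
204338_s_at	RGS4	5999	40
206826_at	PMP2	5375	40
211959_at	IGFBP5	3488	40
213274_s_at	CTSB	1508	40
213791_at	PENK	5179	40
214980_at	UBE3A	7337	40
227062_at	NEAT1	283131	40
229676_at	MTPAP	55149	40
229793_at	ASAH2B	653308	40
235060_at	LOC100190986	100190986	40
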