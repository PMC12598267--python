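gene_id	cds_pos	motif
CG3	281	ACA
CG3	297	CGA
CG3	430	AAAGAG
CG10	1513	AT
CG13	676	AAC
CG13	1723	CAA
CG15	128	AA
CG15	1754	GAA
CG17	617	CAG
CG17	628	CAA
CG24	202	GGA
CG25	1959	GAGGAA
CG25	2000	AAG
CG25	2411	AGA
CG26	85	ATC
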