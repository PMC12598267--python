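gene_id	sanger	hap1_cds_len	hap2_cds_len	pairwise_identity
CG1	1	2793	2793	98.8
CG2	1	1569	1569	98.8
CG3	0	1941	1935	99.1
CG4	1	2124	2124	99.9
CG5	0	1743	1743	98.5
CG6	1	1086	1149	95.6
CG7	0	3075	3075	98.8
CG8	1	420	477	NA
CG9	0	1917	1917	99.0
CG10	0	1137	1281	81.2
CG11	1	2118	2118	99.6
CG12	0	1887	1887	94.6
CG13	1	1806	1806	99.7
CG14	1	2118	2118	99.9
CG15	0	3696	2676	96.2
CG16	1	1491	NA	NA
CG17	1	1068	1068	97.9
CG18	1	672	672	99.8
CG19	0	2775	2751	92.9
CG20	1	1071	1071	96.4
CG21	1	1983	1983	99.0
CG22	0	1956	1956	98.9
CG23	0	1713	1713	98.9
CG24	0	3024	3003	98.9
CG25	0	3021	NA	62.6
CG26	0	3594	3495	94.6
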