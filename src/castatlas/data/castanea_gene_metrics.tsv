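gene_id	align_identity	align_coverage	map_identity	map_coverage	depth_mean	depth_sd
CG1	99.8	49	99.4	100	9.3	4.7
CG2	96.5	99	97.7	100	14.1	11.0
CG3	99.5	100	98.6	99	10.3	3.4
CG4	99.95	100	99.4	100	10.0	4.4
CG5	NA	NA	99.2	75	8.7	2.9
CG6	99.3	100	94.8	100	24.3	10.1
CG7	99.2	100	96.0	99	11.9	5.6
CG8	98.6	100	79.4	81	19.2	15.0
CG9	NA	NA	98.0	100	17.9	8.5
CG10	98.4	86	97.5	97	26.5	15.2
CG11	99.4	100	99.2	100	8.4	4.5
CG12	97.4	72	98.1	100	30	33.0
CG13	99.0	91	99.0	100	10.6	4.3
CG14	99.9	96	99.3	100	10.1	4.3
CG15	NA	NA	98.0	93	9.0	4.2
CG16	97.8	83	99.1	83	29.1	18.8
CG17	98.5	100	98.9	99	8.0	3.5
CG18	99.7	99	96.9	100	15.6	6.0
CG19	99.7	87	98.9	100	7.5	3.7
CG20	97.6	93	99.5	97	7.7	5.7
CG21	99.1	99	98.0	100	17.2	6.7
CG22	98.6	99	98.0	100	17.4	6.8
CG23	97.1	94	98.4	100	12.2	6.1
CG24	99.4	79	97.6	100	10.2	4.4
CG25	99.1	80	93.8	91	13.5	6.3
CG26	99.3	55	98.1	100	11.5	5.5
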