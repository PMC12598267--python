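gene_id	description	response	stress	signal	tf
CG1	Probable disease resistance protein At1g58602	1	1	0	0
CG2	Cytochrome P450 CYP82D47-like	1	1	0	0
CG3	Uncharacterized protein LOC115982017	0	0	1	0
CG4	Heat shock cognate protein 80-like	1	1	0	0
CG5	Wall-associated receptor kinase 2-like	0	0	1	0
CG6	Putative peroxidase 48	0	1	0	0
CG7	Putative inactive disease susceptibility protein LOV1	1	1	0	0
CG8	Oleosin 5-like	1	1	0	0
CG9	Alpha-dioxygenase 1-like	1	1	0	0
CG10	Protein DETOXIFICATION 16-like isoform X1	1	0	0	0
CG11	Heat shock cognate protein 80-like	1	1	0	0
CG12	ATP-dependent DNA helicase 2 subunit KU70	1	1	0	0
CG13	WRKY transcription factor WRKY24-like	0	0	0	1
CG14	Heat shock protein 83	1	1	0	0
CG15	Probable disease resistance RPP8-like protein 2 isoform X3	1	1	0	0
CG16	Two-component response regulator ARR2-like isoform X1	0	0	0	1
CG17	Transcription factor TCP9	0	0	0	1
CG18	Probable glutathione S-transferase	1	0	0	0
CG19	Putative disease resistance RPP13-like protein 3	1	1	0	0
CG20	Serine/threonine-protein kinase SRK2A-like isoform X2	0	0	1	0
CG21	UV-stimulated scaffold protein A homolog	1	1	0	0
CG22	UV-stimulated scaffold protein A homolog	1	1	0	0
CG23	MLO-like protein 6	1	1	0	0
CG24	Protein argonaute 5-like	1	1	0	0
CG25	Putative disease resistance protein RGA3	1	1	0	0
CG26	Probable disease resistance RPP8-like protein 2	1	1	0	0
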