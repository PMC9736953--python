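# Published catalogue of the 40 pathogenic / likely-pathogenic variants identified by
# targeted sequencing of LDLR, APOB, PCSK9 and LDLRAP1 in a Malaysian community
# screening study (5,130 adults screened, 372 clinically diagnosed FH, 82 carriers).
# reported_class is the classification printed in the source report (P pooled
# pathogenic, LP likely pathogenic); evidence holds the ACMG codes it printed.
# n_individuals is the number of carriers reported per variant.
gene	hgvs_c	protein_change	variant_type	exon_or_intron	n_individuals	rsid	polyphen	sift	revel	evidence	reported_class
LDLR	c.241C>T	R81C	missense	3	1	rs730882078	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	P
LDLR	c.301G>A	E101K	missense	3	4	rs144172724	probably_damaging	deleterious	likely_disease_causing	PS3,PM1,PM2,PP2,PP3,PP4,PP5	P
LDLR	c.580A>G	S194G	missense	4	1	rs373488885	benign	tolerated	likely_benign	PM1,PM2,PP2,PP4	LP
LDLR	c.811G>A	V271I	missense	5	1	rs749220643	benign	tolerated	likely_benign	PM1,PM2,PP2,PP4,PP5	LP
LDLR	c.833G>A	G278E	missense	6	1	.	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4	LP
LDLR	c.949G>A	E317K	missense	7	2	rs746834464	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.1234A>C	M412L	missense	9	1	rs1225797407	benign	tolerated	likely_benign	PM1,PM2,PP2,PP4,PP5	LP
LDLR	c.1284C>G	N428K	missense	9	4	rs368708058	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.1289T>G	V430G	missense	9	1	.	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PM5,PP2,PP3,PP4	LP
LDLR	c.1571T>G	V524G	missense	10	1	.	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.1774G>T	G592W	missense	12	6	.	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PM5,PP2,PP3,PP4	LP
LDLR	c.1820A>G	H607R	missense	12	1	rs879255033	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.2383C>G	P795A	missense	16	1	.	probably_damaging	deleterious	likely_disease_causing	PM2,PM5,PP2,PP3,PP4	LP
LDLR	c.2530G>A	G844S	missense	17	1	rs1555809614	probably_damaging	deleterious	likely_disease_causing	PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.1217G>A	R406Q	missense	9	1	rs552422789	probably_damaging	deleterious	likely_disease_causing	PM1,PM2,PP2,PP3,PP4,PP5	LP
LDLR	c.1246C>T	R416W	missense	9	1	rs570942190	probably_damaging	deleterious	likely_disease_causing	PS3,PM1,PM2,PP2,PP3,PP4,PP5	P
LDLR	c.1867A>G	I623V	missense	13	2	rs555292896	benign	tolerated	likely_disease_causing	PM1,PM2,PP2,PP4	LP
LDLR	c.1187-2A>G	.	splice_acceptor	intron 8	1	rs879254823	NA	NA	NA	PVS1,PM1,PM2,PP4,PP5	P
APOB	c.11303T>C	I3768T	missense	26	2	rs376825639	probably_damaging	deleterious	likely_benign	PM1,PM2,PP4,PP5	LP
APOB	c.11006T>G	L3669R	missense	26	1	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PM5,PP3,PP4	LP
APOB	c.9533A>C	K3178T	missense	26	1	.	possibly_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.9107C>A	S3036Y	missense	26	2	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.8287A>C	K2763Q	missense	26	1	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.7975C>T	P2659S	missense	26	1	.	possibly_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.7828G>C	A2610P	missense	26	1	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.5756T>C	L1919P	missense	26	1	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.4951G>A	G1651R	missense	26	2	rs748424949	possibly_damaging	deleterious	likely_benign	PM1,PM2,PP1,PP3,PP4	LP
APOB	c.4867G>A	G1623S	missense	26	1	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.1400C>G	A467G	missense	11	3	rs376602710	probably_damaging	deleterious	likely_disease_causing	PM2,PP3,PP4,PP5	LP
APOB	c.10579C>T	R3527W	missense	26	1	rs144467873	probably_damaging	deleterious	likely_disease_causing	PS3,PM1,PM2,PP3,PP4	P
APOB	c.8462C>T	P2821L	missense	26	2	rs72653095	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.7619G>T	G2540V	missense	26	1	rs571626569	possibly_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
APOB	c.13028_13029del	Y4343fs	frameshift	29	4	rs760832994	NA	NA	NA	PVS1,PS4,PM1,PM2,PP4,PP5	P
PCSK9	c.323T>G	L108R	missense	2	1	.	probably_damaging	deleterious	likely_benign	PS3,PM1,PM2,PP3,PP4,PP5	P
PCSK9	c.1493A>C	E498A	missense	9	31	.	probably_damaging	deleterious	likely_benign	PM1,PM2,PP3,PP4	LP
PCSK9	c.1495C>G	R499G	missense	9	4	.	possibly_damaging	tolerated	likely_benign	PM1,PM2,PM5,PP4	LP
PCSK9	c.212C>T	P71L	missense	2	2	rs569379713	benign	deleterious	likely_benign	PM1,PM2,PP4,PP5	LP
PCSK9	c.286C>T	R96C	missense	2	1	rs185392267	probably_damaging	deleterious	likely_benign	PS3,PM1,PM2,PP3,PP4,PP5	P
LDLRAP1	c.281C>A	P94Q	missense	3	2	.	probably_damaging	deleterious	likely_benign	PM2,PM3,PP3,PP4	LP
LDLRAP1	c.604delT	.	frameshift	6	1	.	NA	NA	NA	PVS1,PM1,PM2,PM3,PP5	P
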