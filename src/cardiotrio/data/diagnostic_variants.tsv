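# Per-variant transcription of the published per-patient mutation table for the 29
# diagnosed cases (hg19 genomic positions as printed). One row per reported allele;
# compound heterozygotes (cases 13, 20, 21) and the two-gene double heterozygote
# (case 32) span two rows. ref/alt are "." where the printed change is not a simple
# SNV (indels, the large duplication); pos is the leftmost printed coordinate and
# end is only set for the large duplication (case 30). zygosity/origin reproduce the
# printed "Zygosity / Inheritance" cells per allele.
case_id	gene	chrom	pos	end	ref	alt	consequence	zygosity	origin	clinical_class	cdna
2	ACTC1	chr15	35085595	.	T	C	missense	hetero	father	likely_pathogenic	c.305A>G
3	TNNT2	chr1	201331116	.	C	T	missense	hetero	de_novo	pathogenic	c.614G>A
5	PTPN11	chr12	112888202	.	C	T	missense	hetero	de_novo	pathogenic	c.218C>T
6	RAF1	chr3	12645682	.	.	.	inframe	hetero	de_novo	pathogenic	c.785_787del
7	PRKAG2	chr7	151257696	.	C	T	missense	hetero	de_novo	pathogenic	c.1592G>A
8	TNNI3	chr19	55668662	.	A	T	splice	homo	both	likely_pathogenic	c.24+2T>A
12	HADHB	chr2	26502860	.	A	G	splice	homo	both	likely_pathogenic	c.812-2A>G
13	GAA	chr17	78078910	.	.	.	lof	hetero	father	pathogenic	c.525del
13	GAA	chr17	78090909	.	G	A	splice	hetero	mother	pathogenic	c.2331+1G>A
14	HCCS	chrX	11139015	.	G	A	splice	hetero	de_novo	likely_pathogenic	c.522-12G>A
17	PTPN11	chr12	112926270	.	C	T	missense	hetero	de_novo	pathogenic	c.1403C>T
18	RAF1	chr3	12645699	.	G	A	missense	hetero	de_novo	pathogenic	c.770C>T
19	FAH	chr15	80450512	.	G	T	missense	homo	both	pathogenic	c.192G>T
20	GAA	chr17	78078910	.	.	.	lof	hetero	father	pathogenic	c.525del
20	GAA	chr17	78079671	.	C	T	missense	hetero	mother	pathogenic	c.670C>T
21	HADHB	chr2	26505741	.	.	.	lof	hetero	mother	likely_pathogenic	c.962del
21	HADHB	chr2	26502860	.	A	G	splice	hetero	father	likely_pathogenic	c.812-2A>G
22	TAZ	chrX	153640263	.	.	.	lof	hemi	mother	likely_pathogenic	c.83_86del
24	VPS33A	chr12	122717464	.	G	A	missense	homo	both	pathogenic	c.1492C>T
26	POU1F1	chr3	87310439	.	G	A	lof	homo	both	likely_pathogenic	c.649C>T
27	PTPN11	chr12	112926908	.	C	G	missense	hetero	de_novo	pathogenic	c.1528C>G
28	HRAS	chr11	534288	.	C	T	missense	hetero	de_novo	pathogenic	c.35G>A
30	ATAD3A	chr1	1392270	1460317	.	.	other	hetero	de_novo	pathogenic	dup
32	MYL2	chr12	111356937	.	C	T	missense	hetero	mother	pathogenic	c.64G>A
32	MYH7	chr14	23887522	.	C	T	missense	hetero	father	pathogenic	c.4066G>A
33	PTPN11	chr12	112910827	.	A	G	missense	hetero	de_novo	pathogenic	c.836A>G
35	MYH7	chr14	23886789	.	C	T	missense	hetero	mother	likely_pathogenic	c.4276G>A
36	MYH7	chr14	23886717	.	C	T	missense	hetero	de_novo	likely_pathogenic	c.4348G>A
37	MYH7	chr14	23887513	.	G	A	missense	hetero	father	likely_pathogenic	c.4075C>T
38	PTPN11	chr12	112910827	.	A	G	missense	hetero	de_novo	pathogenic	c.836A>G
40	NONO	chrX	70514185	.	C	T	lof	hemi	mother	pathogenic	c.457C>T
41	TNNI3	chr19	55667648	.	.	.	lof	homo	both	likely_pathogenic	c.204del
42	TNNI3	chr19	55667648	.	.	.	lof	homo	both	likely_pathogenic	c.204del
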