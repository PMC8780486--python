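# Cohort of 42 consecutive infants (<=12 months) with cardiomyopathy who underwent
# trio whole-exome sequencing. Diagnosed rows transcribe the source study's published
# per-patient table; case_id preserves that table's row ID. The 13 undiagnosed cases
# carry the IDs absent from the published per-patient table; their sex/age/type/class
# cells are a synthetic assignment chosen to satisfy every published stratum total
# (they are not individually published). family_history and prenatal are case-level
# booleans whose per-row assignment is synthetic; only their stratum counts are
# published (5 family history: 3 urgent / 2 non-urgent; 9 prenatal: 5 / 4).
# t1_days/t2_days are absent throughout: only summary turnaround statistics are
# published, never per-patient times.
# cm_class: isolated | syndromic | metabolic (clinical classification at enrolment).
# zygosity: hetero | homo | hemi | compound_het; parental_origin: de_novo | mother |
# father | both ("both" = biallelic for homo/compound_het, one allele per parent;
# for case 32 it marks two heterozygous variants in two genes, one per parent).
case_id	urgent	age_months	sex	cm_type	cm_class	diagnosed	gene	zygosity	parental_origin	family_history	prenatal	t1_days	t2_days
1	yes	1	M	HCM	syndromic	no	.	.	.	no	yes	.	.
2	no	7	M	DCM	isolated	yes	ACTC1	hetero	father	no	no	.	.
3	no	3	F	DCM	isolated	yes	TNNT2	hetero	de_novo	no	no	.	.
4	yes	1	M	HCM	syndromic	no	.	.	.	no	no	.	.
5	yes	1	M	HCM	isolated	yes	PTPN11	hetero	de_novo	no	no	.	.
6	no	1	M	HCM	syndromic	yes	RAF1	hetero	de_novo	no	no	.	.
7	yes	1	M	HCM	syndromic	yes	PRKAG2	hetero	de_novo	no	no	.	.
8	yes	12	F	DCM	isolated	yes	TNNI3	homo	both	yes	no	.	.
9	yes	2	M	HCM	syndromic	no	.	.	.	no	no	.	.
10	yes	3	M	DCM	syndromic	no	.	.	.	no	no	.	.
11	yes	3	F	HCM	syndromic	no	.	.	.	no	no	.	.
12	yes	4	F	HCM	metabolic	yes	HADHB	homo	both	no	yes	.	.
13	yes	6	F	HCM	isolated	yes	GAA	compound_het	both	no	no	.	.
14	yes	3	F	HCM	syndromic	yes	HCCS	hetero	de_novo	no	no	.	.
15	yes	4	F	HCM	metabolic	no	.	.	.	no	no	.	.
16	yes	5	F	HCM	metabolic	no	.	.	.	no	no	.	.
17	no	1	F	HCM	syndromic	yes	PTPN11	hetero	de_novo	no	no	.	.
18	no	0	M	HCM	syndromic	yes	RAF1	hetero	de_novo	no	yes	.	.
19	yes	3	M	HCM	metabolic	yes	FAH	homo	both	no	no	.	.
20	yes	10	F	HCM	metabolic	yes	GAA	compound_het	both	no	no	.	.
21	yes	1	F	HCM	metabolic	yes	HADHB	compound_het	both	no	yes	.	.
22	yes	9	M	DCM	metabolic	yes	TAZ	hemi	mother	no	no	.	.
23	no	1	M	HCM	syndromic	no	.	.	.	yes	no	.	.
24	yes	11	M	HCM	metabolic	yes	VPS33A	homo	both	no	no	.	.
25	no	2	M	HCM	syndromic	no	.	.	.	no	yes	.	.
26	yes	3	M	HCM	metabolic	yes	POU1F1	homo	both	no	no	.	.
27	yes	0	M	HCM	syndromic	yes	PTPN11	hetero	de_novo	no	no	.	.
28	yes	0	M	HCM	syndromic	yes	HRAS	hetero	de_novo	no	yes	.	.
29	no	3	M	HCM	syndromic	no	.	.	.	no	no	.	.
30	yes	1	F	HCM	metabolic	yes	ATAD3A	hetero	de_novo	no	yes	.	.
31	no	3	M	DCM	syndromic	no	.	.	.	no	yes	.	.
32	no	0	M	HCM	isolated	yes	MYL2;MYH7	hetero	both	no	no	.	.
33	no	5	M	HCM	syndromic	yes	PTPN11	hetero	de_novo	no	no	.	.
34	no	4	M	HCM	metabolic	no	.	.	.	no	no	.	.
35	no	2	M	DCM	isolated	yes	MYH7	hetero	mother	yes	no	.	.
36	no	12	M	HCM	isolated	yes	MYH7	hetero	de_novo	no	no	.	.
37	no	7	M	DCM	isolated	yes	MYH7	hetero	father	no	no	.	.
38	no	8	F	HCM	syndromic	yes	PTPN11	hetero	de_novo	no	no	.	.
39	no	4	F	DCM	isolated	no	.	.	.	no	no	.	.
40	no	3	M	DCM	syndromic	yes	NONO	hemi	mother	no	yes	.	.
41	yes	9	F	DCM	isolated	yes	TNNI3	homo	both	yes	no	.	.
42	yes	10	F	DCM	isolated	yes	TNNI3	homo	both	yes	no	.	.
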