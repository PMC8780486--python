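# Gene -> etiological class map for the diagnosed cohort, mirroring the published
# class assignments: metabolic_mito (inborn errors of metabolism / mitochondrial),
# sarcomeric, rasopathy, ultra_rare (ultra-rare syndromic disorders).
gene	etiology
ACTC1	sarcomeric
TNNT2	sarcomeric
TNNI3	sarcomeric
MYH7	sarcomeric
MYL2	sarcomeric
PTPN11	rasopathy
RAF1	rasopathy
HRAS	rasopathy
PRKAG2	metabolic_mito
HADHB	metabolic_mito
GAA	metabolic_mito
FAH	metabolic_mito
TAZ	metabolic_mito
VPS33A	metabolic_mito
POU1F1	metabolic_mito
ATAD3A	metabolic_mito
NONO	ultra_rare
HCCS	ultra_rare
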