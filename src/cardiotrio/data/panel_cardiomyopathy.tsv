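# Cardiomyopathy gene panel (curated green-list style). modes: comma-joined subset
# of AD,AR,XL. mechanism: expected pathogenic mechanism — lof (loss of function),
# non_lof (e.g. activating/dominant-negative missense), either.
symbol	modes	mechanism	tags
ACTC1	AD	non_lof	sarcomeric
TNNT2	AD	non_lof	sarcomeric
MYH7	AD	non_lof	sarcomeric
MYL2	AD	non_lof	sarcomeric
MYBPC3	AD	either	sarcomeric
TNNI3	AD,AR	either	sarcomeric
TTN	AD	lof	sarcomeric
PTPN11	AD	non_lof	rasopathy
RAF1	AD	non_lof	rasopathy
HRAS	AD	non_lof	rasopathy
PRKAG2	AD	non_lof	metabolic
GAA	AR	either	metabolic
HADHB	AR	either	metabolic
FAH	AR	either	metabolic
VPS33A	AR	non_lof	metabolic
POU1F1	AR	either	endocrine
AGL	AR	lof	metabolic
ELAC2	AR	either	mitochondrial
ALPK3	AR	lof	sarcomeric
JPH2	AD,AR	either	sarcomeric
LMNA	AD	either	laminopathy
DES	AD	either	desminopathy
ATAD3A	AD	either	mitochondrial
TAZ	XL	either	mitochondrial
NONO	XL	lof	syndromic
HCCS	XL	either	syndromic
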