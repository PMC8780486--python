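# Synthetic toy gene intervals emulating the ATAD3 paralog cluster on chr1
# (hg19-like coordinates; 0-based half-open BED). A duplication spanning
# chr1:1392270-1460317 (1-based) overlaps all three members.
chr1	1385068	1405538	ATAD3C	0	+
chr1	1407142	1433228	ATAD3B	0	+
chr1	1447530	1470067	ATAD3A	0	+
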