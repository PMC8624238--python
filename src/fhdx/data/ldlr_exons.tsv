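exon	cdna_end
1	67
10	1586
14	2140
15	2311
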