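# segregation_counts.tsv: observed regrowth (R) / non-regrowth (NR) counts per generation, as published
generation	total	n_R	n_NR
B73-Zd-F2	134	81	53
B73-Zd-F3	72	52	20
Zd-RF-F2	160	92	68
Zd-RF-F3-3	15	12	3
Zd-RF-F3-5	16	9	7
Zd-RF-F3-9	16	13	3
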