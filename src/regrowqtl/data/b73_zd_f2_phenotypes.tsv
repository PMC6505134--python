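# b73_zd_f2_phenotypes.tsv: B73 x Z. diploperennis F2 phenotypes and gt1/tb1/id1 marker genotypes
# gbs flags for plants BZ2-001-1 and BZ2-002-1 were restored so the table matches the
# published tally of 83 GBS-included plants (46 R, 37 NR); the available transcription marked only 81
# role: parent|f2; gbs: 1 if plant was used for GBS SNP calling; genotype codes 1=Zd hom, 2=maize hom, 3=het, -=missing
plant	role	gbs	phenotype	gt1	tb1	id1
Zea diploperennis	parent	1	R	1	1	1
BZ2-006-9	f2	1	R	1	1	2
BZ2-009-6	f2	0	R	1	1	2
B73	parent	0	NR	2	2	2
BZ2-006-10	f2	1	R	1	3	2
BZ2-009-7	f2	0	NR	1	-	2
BZ2-001-1	f2	1	R	1	3	2
BZ2-006-11	f2	0	NR	3	2	2
BZ2-009-8	f2	1	NR	3	2	2
BZ2-001-2	f2	0	R	3	3	1
BZ2-006-12	f2	1	NR	3	3	2
BZ2-009-9	f2	1	R	3	1	2
BZ2-001-3	f2	0	R	1	3	2
BZ2-006-13	f2	0	NR	3	2	1
BZ2-009-10	f2	1	NR	1	3	2
BZ2-001-4	f2	0	R	1	3	2
BZ2-006-14	f2	1	R	3	2	2
BZ2-009-11	f2	0	R	1	3	2
BZ2-001-5	f2	1	R	1	1	2
BZ2-007-1	f2	1	NR	3	2	2
BZ2-009-12	f2	1	R	3	3	2
BZ2-002-1	f2	1	NR	1	3	2
BZ2-007-2	f2	0	NR	3	2	2
BZ2-010-1	f2	1	R	3	2	2
BZ2-002-2	f2	0	NR	1	2	2
BZ2-007-3	f2	1	R	1	2	2
BZ2-010-2	f2	1	NR	-	3	2
BZ2-002-3	f2	0	R	3	3	2
BZ2-007-4	f2	0	R	3	2	2
BZ2-010-3	f2	1	R	3	1	2
BZ2-002-4	f2	0	R	3	2	1
BZ2-007-5	f2	1	R	3	3	2
BZ2-010-4	f2	0	R	3	2	1
BZ2-002-5	f2	0	NR	3	3	2
BZ2-007-6	f2	1	NR	3	3	2
BZ2-010-5	f2	1	NR	3	1	2
BZ2-002-6	f2	0	NR	3	2	2
BZ2-007-7	f2	1	R	1	3	2
BZ2-010-6	f2	1	R	3	2	2
BZ2-002-7	f2	1	NR	3	2	2
BZ2-007-8	f2	0	R	3	1	2
BZ2-010-7	f2	1	NR	3	1	2
BZ2-002-8	f2	0	R	1	-	2
BZ2-007-9	f2	0	R	3	1	2
BZ2-010-8	f2	1	R	3	2	2
BZ2-002-9	f2	1	R	3	2	2
BZ2-007-10	f2	1	NR	1	3	2
BZ2-010-9	f2	1	R	1	3	2
BZ2-002-10	f2	1	R	3	3	2
BZ2-007-11	f2	0	NR	3	1	2
BZ2-010-10	f2	1	R	3	2	2
BZ2-002-11	f2	1	NR	1	2	1
BZ2-007-12	f2	1	R	1	2	2
BZ2-010-11	f2	1	R	2	3	2
BZ2-002-12	f2	0	R	1	2	2
BZ2-007-13	f2	1	R	3	1	2
BZ2-010-12	f2	1	NR	2	3	2
BZ2-002-13	f2	0	R	3	3	2
BZ2-007-14	f2	1	NR	1	3	2
BZ2-010-13	f2	1	R	3	3	2
BZ2-002-14	f2	0	NR	1	1	2
BZ2-007-15	f2	0	NR	3	1	2
BZ2-010-14	f2	0	R	1	2	2
BZ2-002-15	f2	0	R	1	3	1
BZ2-007-16	f2	1	R	1	3	2
BZ2-010-15	f2	1	NR	3	3	2
BZ2-002-16	f2	0	R	3	3	1
BZ2-007-17	f2	1	NR	1	-	1
BZ2-010-16	f2	1	NR	1	3	2
BZ2-002-17	f2	1	NR	3	2	2
BZ2-007-18	f2	1	R	1	1	2
BZ2-010-17	f2	0	R	1	3	2
BZ2-002-18	f2	1	R	1	2	2
BZ2-007-19	f2	1	R	3	2	2
BZ2-010-18	f2	1	NR	3	3	2
BZ2-002-19	f2	0	R	1	2	2
BZ2-007-20	f2	1	R	3	2	2
BZ2-010-19	f2	1	R	2	2	1
BZ2-002-20	f2	0	R	1	2	2
BZ2-007-21	f2	1	NR	3	2	2
BZ2-010-20	f2	1	NR	1	2	1
BZ2-002-21	f2	1	R	1	2	1
BZ2-008-1	f2	0	R	1	1	2
BZ2-010-21	f2	0	NR	3	3	2
BZ2-002-22	f2	1	R	3	2	2
BZ2-008-2	f2	1	R	3	1	2
BZ2-011-1	f2	0	NR	1	-	1
BZ2-002-23	f2	1	R	3	2	1
BZ2-008-3	f2	0	R	3	1	2
BZ2-011-2	f2	1	R	3	2	2
BZ2-002-24	f2	0	R	3	2	2
BZ2-008-4	f2	0	NR	3	2	2
BZ2-011-3	f2	0	R	2	3	2
BZ2-002-25	f2	0	NR	1	2	2
BZ2-008-5	f2	1	R	3	3	2
BZ2-011-4	f2	1	R	3	1	2
BZ2-004-1	f2	0	R	3	1	2
BZ2-008-6	f2	1	NR	3	2	2
BZ2-011-5	f2	0	R	1	-	1
BZ2-004-2	f2	0	R	1	3	2
BZ2-008-7	f2	1	NR	3	3	2
BZ2-011-6	f2	1	NR	3	2	2
BZ2-004-3	f2	1	NR	3	2	2
BZ2-008-8	f2	1	R	3	2	2
BZ2-011-7	f2	1	NR	1	2	2
BZ2-004-4	f2	0	R	1	3	2
BZ2-008-9	f2	1	NR	3	2	2
BZ2-011-8	f2	1	NR	2	1	1
BZ2-004-5	f2	1	R	3	2	2
BZ2-008-10	f2	1	R	1	1	2
BZ2-011-9	f2	1	R	3	2	2
BZ2-004-6	f2	1	R	3	1	2
BZ2-008-11	f2	1	NR	3	2	2
BZ2-011-10	f2	0	R	3	1	2
BZ2-006-1	f2	1	NR	3	1	2
BZ2-008-12	f2	1	R	3	3	2
BZ2-011-11	f2	0	R	1	2	2
BZ2-006-2	f2	0	NR	1	1	2
BZ2-008-13	f2	1	R	1	2	2
BZ2-011-12	f2	1	R	1	3	2
BZ2-006-3	f2	0	R	3	3	2
BZ2-008-14	f2	1	NR	1	3	2
BZ2-011-13	f2	1	R	3	1	2
BZ2-006-4	f2	0	R	3	2	2
BZ2-009-1	f2	1	NR	3	3	2
BZ2-011-14	f2	1	NR	3	1	2
BZ2-006-5	f2	0	R	3	3	2
BZ2-009-2	f2	0	R	1	3	1
BZ2-011-15	f2	0	NR	3	3	2
BZ2-006-6	f2	1	NR	3	3	2
BZ2-009-3	f2	1	NR	3	2	2
BZ2-011-16	f2	1	NR	1	2	2
BZ2-006-7	f2	1	R	3	1	2
BZ2-009-4	f2	1	R	1	3	2
BZ2-006-8	f2	0	R	3	1	2
BZ2-009-5	f2	1	NR	3	3	2
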