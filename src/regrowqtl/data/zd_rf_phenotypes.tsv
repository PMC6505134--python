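# zd_rf_phenotypes.tsv: Z. diploperennis x Rhee Flint F2 (ZR2) and F3 (ZR3) regrowth phenotypes
plant	generation	phenotype
ZR2-001-1	f2	R
ZR2-001-59	f2	R
ZR2-001-116	f2	R
ZR2-001-168	f2	NR
ZR2-001-2	f2	NR
ZR2-001-60	f2	R
ZR2-001-117	f2	R
ZR2-001-169	f2	NR
ZR2-001-3	f2	R
ZR2-001-62	f2	R
ZR2-001-118	f2	NR
ZR2-001-171	f2	R
ZR2-001-4	f2	NR
ZR2-001-63	f2	R
ZR2-001-119	f2	R
ZR3-003-1	f3-3	R
ZR2-001-5	f2	R
ZR2-001-64	f2	R
ZR2-001-120	f2	R
ZR3-003-2	f3-3	R
ZR2-001-6	f2	R
ZR2-001-65	f2	R
ZR2-001-121	f2	NR
ZR3-003-3	f3-3	R
ZR2-001-7	f2	NR
ZR2-001-67	f2	NR
ZR2-001-122	f2	R
ZR3-003-4	f3-3	NR
ZR2-001-9	f2	R
ZR2-001-68	f2	NR
ZR2-001-123	f2	NR
ZR3-003-6	f3-3	R
ZR2-001-10	f2	NR
ZR2-001-69	f2	NR
ZR2-001-124	f2	R
ZR3-003-7	f3-3	R
ZR2-001-11	f2	R
ZR2-001-71	f2	R
ZR2-001-125	f2	R
ZR3-003-8	f3-3	R
ZR2-001-12	f2	R
ZR2-001-72	f2	NR
ZR2-001-126	f2	NR
ZR3-003-9	f3-3	R
ZR2-001-13	f2	NR
ZR2-001-73	f2	R
ZR2-001-127	f2	NR
ZR3-003-10	f3-3	R
ZR2-001-14	f2	NR
ZR2-001-74	f2	R
ZR2-001-128	f2	NR
ZR3-003-11	f3-3	NR
ZR2-001-15	f2	R
ZR2-001-75	f2	R
ZR2-001-129	f2	R
ZR3-003-12	f3-3	R
ZR2-001-16	f2	NR
ZR2-001-77	f2	NR
ZR2-001-130	f2	NR
ZR3-003-13	f3-3	R
ZR2-001-17	f2	R
ZR2-001-78	f2	NR
ZR2-001-131	f2	NR
ZR3-003-14	f3-3	R
ZR2-001-18	f2	NR
ZR2-001-79	f2	R
ZR2-001-132	f2	NR
ZR3-003-15	f3-3	R
ZR2-001-19	f2	NR
ZR2-001-80	f2	R
ZR2-001-133	f2	R
ZR3-003-16	f3-3	NR
ZR2-001-20	f2	R
ZR2-001-81	f2	R
ZR2-001-134	f2	R
ZR3-005-1	f3-5	R
ZR2-001-21	f2	NR
ZR2-001-82	f2	NR
ZR2-001-135	f2	NR
ZR3-005-2	f3-5	R
ZR2-001-22	f2	NR
ZR2-001-83	f2	NR
ZR2-001-136	f2	NR
ZR3-005-3	f3-5	NR
ZR2-001-23	f2	R
ZR2-001-84	f2	R
ZR2-001-137	f2	R
ZR3-005-4	f3-5	NR
ZR2-001-24	f2	R
ZR2-001-85	f2	R
ZR2-001-138	f2	R
ZR3-005-5	f3-5	R
ZR2-001-25	f2	NR
ZR2-001-86	f2	R
ZR2-001-139	f2	R
ZR3-005-6	f3-5	R
ZR2-001-26	f2	R
ZR2-001-87	f2	NR
ZR2-001-140	f2	NR
ZR3-005-7	f3-5	R
ZR2-001-27	f2	NR
ZR2-001-88	f2	NR
ZR2-001-141	f2	R
ZR3-005-8	f3-5	R
ZR2-001-28	f2	NR
ZR2-001-89	f2	NR
ZR2-001-142	f2	R
ZR3-005-9	f3-5	R
ZR2-001-30	f2	R
ZR2-001-90	f2	R
ZR2-001-143	f2	R
ZR3-005-10	f3-5	R
ZR2-001-31	f2	R
ZR2-001-91	f2	R
ZR2-001-144	f2	NR
ZR3-005-11	f3-5	NR
ZR20-01-32	f2	R
ZR2-001-92	f2	R
ZR2-001-145	f2	R
ZR3-005-12	f3-5	NR
ZR2-001-33	f2	NR
ZR2-001-93	f2	R
ZR2-001-146	f2	R
ZR3-005-13	f3-5	R
ZR2-001-34	f2	R
ZR2-001-94	f2	NR
ZR2-001-147	f2	R
ZR3-005-14	f3-5	NR
ZR2-001-35	f2	NR
ZR2-001-95	f2	NR
ZR2-001-148	f2	R
ZR3-005-15	f3-5	NR
ZR2-001-36	f2	NR
ZR2-001-97	f2	R
ZR2-001-149	f2	R
ZR3-005-16	f3-5	NR
ZR2-001-37	f2	NR
ZR2-001-98	f2	R
ZR2-001-150	f2	R
ZR3-009-1	f3-9	R
ZR2-001-38	f2	NR
ZR2-001-99	f2	R
ZR2-001-151	f2	R
ZR3-009-2	f3-9	R
ZR2-001-39	f2	R
ZR2-001-100	f2	R
ZR2-001-152	f2	NR
ZR3-009-3	f3-9	R
ZR2-001-40	f2	NR
ZR2-001-101	f2	R
ZR2-001-153	f2	R
ZR3-009-4	f3-9	R
ZR2-001-42	f2	NR
ZR2-001-102	f2	R
ZR2-001-154	f2	R
ZR3-009-5	f3-9	R
ZR2-001-43	f2	R
ZR2-001-103	f2	R
ZR2-001-155	f2	NR
ZR3-009-6	f3-9	NR
ZR2-001-44	f2	R
ZR2-001-104	f2	R
ZR2-001-156	f2	R
ZR3-009-7	f3-9	R
ZR2-001-45	f2	R
ZR2-001-105	f2	R
ZR2-001-157	f2	NR
ZR3-009-8	f3-9	R
ZR2-001-47	f2	NR
ZR2-001-106	f2	R
ZR2-001-158	f2	NR
ZR3-009-9	f3-9	R
ZR2-001-48	f2	NR
ZR2-001-107	f2	NR
ZR2-001-159	f2	NR
ZR3-009-10	f3-9	R
ZR2-001-49	f2	R
ZR2-001-108	f2	NR
ZR2-001-160	f2	R
ZR3-009-11	f3-9	R
ZR2-001-51	f2	NR
ZR2-001-109	f2	NR
ZR2-001-161	f2	R
ZR3-009-12	f3-9	R
ZR2-001-53	f2	NR
ZR2-001-110	f2	R
ZR2-001-162	f2	NR
ZR3-009-13	f3-9	R
ZR2-001-54	f2	R
ZR2-001-111	f2	NR
ZR2-001-163	f2	R
ZR3-009-14	f3-9	NR
ZR2-001-55	f2	R
ZR2-001-112	f2	R
ZR2-001-164	f2	R
ZR3-009-15	f3-9	NR
ZR2-001-56	f2	R
ZR2-001-113	f2	NR
ZR2-001-165	f2	NR
ZR3-009-16	f3-9	R
ZR2-001-57	f2	R
ZR2-001-114	f2	NR
ZR2-001-166	f2	R
ZR2-001-58	f2	NR
ZR2-001-115	f2	NR
ZR2-001-167	f2	NR
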