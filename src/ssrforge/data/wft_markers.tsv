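locus	scaffold	motif	units	size_min	size_max	na	n	hwe_deviant_pops	ambiguous_peaks	sni	panel
wft3-S01	KL023705	AAT	12	162	246	16	47	1	True	False	MP
wft3-S03	KL023701	AGC	12	135	188	8	45	0	False	False
wft3-S06	KL023747	AGC	8	142	159	5	46	0	False	False
wft3-S08	KL023707	ACG	8	155	173	5	47	0	False	False	SS
wft4-S09	KL023695	AGGC	7	165	185	5	47	1	False	False	SS
wft4-S13	KL023711	AACC	16	157	184	4	47	0	False	False	SS
wft3-S14	KL023717	AAG	22	178	222	10	47	0	False	False	SS
wft4-S16	KL023774	ACAG	14	190	223	8	43	0	False	False
wft4-S17	KL023720	ACAG	20	99	249	10	46	0	False	False
wft3-S20	KL023696	AGC	17	204	271	6	46	0	False	False
wft3-S21	KL023772	AAT	15	243	284	11	45	1	False	False	MP
wft4-S22	KL023713	AGAT	9	240	300	13	46	1	False	True	SNI
wft4-S26	KL023743	ACAG	17	220	321	11	44	1	False	False	MP
wft3-S27	KL023766	ACC	13	224	263	10	44	1	False	True	SNI
wft3-S28	KL023710	ACT	10	236	253	10	47	0	False	True	SNI
wft4-S29	KL023712	ACGC	11	233	272	9	41	0	False	False
wft4-S30	KL023745	ACGG	11	217	336	11	47	1	False	True	SNI
wft4-S31	KL023716	ACTC	13	209	261	11	41	2	False	False	MP
wft4-S32	KL023729	ACAG	16	212	359	17	45	1	False	False	MP
wft3-S33	KL023736	AGC	10	238	255	10	47	0	False	True	SNI
wft4-S34	KL023718	AGAT	13	234	273	9	46	0	False	False
wft4-S36	KL023722	AAAG	10	275	293	6	46	0	False	False
wft3-S43	KL023742	AGC	20	258	299	11	47	0	False	False	MP,SS
wft4-S45	KL023755	ACAG	8	296	320	6	47	0	False	False	SS
wft4-S50	KL023714	ATCC	13	303	351	7	47	0	False	False	SS
wft4-S52	KL023739	AAAC	11	312	366	10	39	0	False	True	SNI
wft3-S53	KL023752	AAC	17	299	357	11	47	1	False	True	SNI
wft4-S57	KL023777	AGAT	23	338	416	13	43	2	False	False	MP
wft4-S58	KL023694	AGAT	15	338	394	12	47	0	False	False	MP,SS
wft3-S60	KL023732	AGC	8	358	383	8	47	0	False	True	SNI
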