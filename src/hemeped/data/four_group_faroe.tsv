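row	pc_abbrev	pc_total	pc_males	pc_females	ratio_mm	ratio_fm	ratio_mf	ratio_ff	obs1_t	obs1_m	obs1_f	obs2_t	obs2_m	obs2_f	obs3_t	obs3_m	obs3_f	obs4_t	obs4_m	obs4_f	tot_t	tot_m	tot_f	exp_t	exp_m	exp_f	s1_t	s1_m	s1_f	s2_t	s2_m	s2_f	s3_t	s3_m	s3_f	s4_t	s4_m	s4_f	scored	flagged
LPD/HL	HL	19	12	7	5.7	4.4	9.7	7.6	65	37	28	25	13	12	13	6	7	18	12	6	121	68	53	30	17	13	3	3	3	0	0	0	-2	-2	0	-1	0	0	1
LPD/NHL FL	FL	14	9	5	4.9	2.2	8.8	4.0	13	12	1	19	12	7	7	2	5	25	18	7	64	44	20	16	11	5	0	0	0	0	0	0	-1	-2	0	0	0	0	1	s4_t_printed_0_recomputes_+1
LPD/NHL DLBCL	DLBCL	34	21	13	4.7	3.9	7.6	6.3	59	32	27	42	23	19	39	24	15	41	20	21	181	99	82	45	25	20	1	0	0	0	0	0	0	0	0	0	0	0	1
LPD/NHL NOS	NHL NOS	25	14	11	5.9	3.7	7.5	4.7	28	19	9	37	22	15	39	23	16	30	18	12	134	82	52	34	21	13	0	0	0	0	0	0	0	0	0	0	0	0	1
LPD/MM	MM	50	31	19	5.8	4.3	9.5	7.0	102	63	39	88	46	42	46	23	23	77	48	29	313	180	133	78	45	33	2	2	0	0	0	0	-3	-3	0	0	0	0	1	s3_m_printed_-3_recomputes_-2
LPD/CLL	CLL	50	29	21	5.0	3.2	7.0	4.5	82	53	29	77	51	26	43	19	24	38	23	15	240	146	94	60	37	23	2	2	0	1	1	0	-1	-2	0	-2	-1	0	1
MM/CLL					.	.	.	.	21	14	7	17	10	7	13	9	4	4	4	0	55	37	18	14	9	5	.	.	.	.	.	.	.	.	.	.	.	.	0	small_sample
CLL/CLL					.	.	.	.	15	10	5	14	7	7	12	9	3	10	4	6	51	30	21	13	8	5	.	.	.	.	.	.	.	.	.	.	.	.	0	small_sample
LPD/ALL	ALL	16	10	6	3.5	1.6	5.8	2.7	19	15	4	10	6	4	7	3	4	15	11	4	51	35	16	13	9	4	0	0	0	0	0	0	0	-1	0	0	0	0	1	s1_m_printed_0_recomputes_+1
LPD/other LPD					.	.	.	.	11	8	3	4	2	2	25	9	16	12	5	7	52	24	28	13	6	7	.	.	.	.	.	.	.	.	.	.	.	.	0	small_sample
LPD/LPD	LPD	219	131	88	5.2	3.6	7.7	5.4	382	239	143	299	175	124	219	111	108	256	153	103	1156	678	478	289	170	119	3	3	1	0	0	0	-3	-3	0	0	0	0	1
MPD/LPD					4.0	2.7	5.9	4.0	85	60	25	64	40	24	25	7	18	63	34	29	237	141	96	59	34	24	3	3	0	0	0	0	-3	-3	0	0	0	0	1	exp_m_printed_34_recomputes_35;ratio_denominator_not_in_cohort_table
LPD/MPD	MPD	87	52	35	3.2	2.4	4.7	3.6	91	54	37	79	44	35	50	21	29	71	45	26	291	164	127	73	41	32	1	1	0	0	0	0	-2	-2	0	0	0	0	1
MPD/MPD	MPD	87	52	35	2.8	1.7	4.2	2.5	95	66	29	66	45	21	28	10	18	47	27	20	236	148	88	59	37	22	3	3	0	0	0	0	-3	-3	0	0	0	0	1
MPD/AML	AML	44	28	16	2.5	1.7	4.4	3.0	41	27	14	32	19	13	17	7	10	28	17	11	118	70	48	30	18	12	1	1	0	0	0	0	-1	-2	0	0	0	0	1
MPD/CML	CML	14	9	5	3.4	2.4	6.2	4.4	21	15	6	12	9	3	8	1	7	12	6	6	53	31	22	13	8	5	1	1	0	0	0	0	0	-1	0	0	0	0	1
MPD/other MPD	OTHER MPD	21	11	10	3.1	1.1	3.4	1.2	26	19	7	16	13	3	2	0	2	2	2	0	46	34	12	12	9	3	3	3	1	0	0	0	-2	-2	0	-2	-1	0	1
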