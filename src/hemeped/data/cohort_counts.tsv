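cohort	group	abbrev	total	males	females	printed_percent	flagged
faroe	LPD	HL	19	12	7	8.7
faroe	LPD	FL	14	9	5	6.4
faroe	LPD	MCL	0	0	0
faroe	LPD	DLBCL	34	21	13	15.6	percent_printed_15.6_recomputes_15.5
faroe	LPD	TNHL	6	2	4	2.7
faroe	LPD	MONOC	0	0	0
faroe	LPD	NHL NOS	25	14	11	11.4
faroe	LPD	WA	2	1	1	0.9
faroe	LPD	MM	50	31	19	22.8
faroe	LPD	ALL	16	10	6	7.3
faroe	LPD	CLL	50	29	21	22.8
faroe	LPD	PLL	2	1	1	0.9
faroe	LPD	HCL	1	1	0	0.5
faroe	LPD	LGTCL	0	0	0
faroe	LPD	MGUS	0	0	0
nordic	LPD	HL	11	8	3	4.0
nordic	LPD	FL	19	13	6	6.9
nordic	LPD	MCL	4	4	0	1.4
nordic	LPD	DLBCL	16	9	7	5.8
nordic	LPD	TNHL	2	2	0	0.7
nordic	LPD	MONOC	4	1	3	1.4
nordic	LPD	NHL NOS	9	4	5	3.3
nordic	LPD	WA	8	5	3	2.9
nordic	LPD	MM	10	6	4	3.6
nordic	LPD	ALL	4	2	2	1.4
nordic	LPD	CLL	181	98	83	65.6
nordic	LPD	PLL	2	0	2	0.7
nordic	LPD	HCL	1	0	1	0.4
nordic	LPD	LGTCL	3	2	1	1.1
nordic	LPD	MGUS	2	1	1	0.7
faroe	MPD	AML	44	28	16	50.6
faroe	MPD	CML	14	9	5	16.1
faroe	MPD	PV	4	2	2	4.6
faroe	MPD	MDS	2	0	2	2.3
faroe	MPD	MF	8	4	4	9.2
faroe	MPD	ET	0	0	0
faroe	MPD	ML NOS	15	9	6	17.2
nordic	MPD	AML	9	6	3	37.6	percent_printed_37.6_recomputes_37.5
nordic	MPD	CML	3	1	2	12.5
nordic	MPD	PV	6	4	2	25.0
nordic	MPD	MDS	2	1	1	8.3
nordic	MPD	MF	1	0	1	4.2
nordic	MPD	ET	3	1	2	12.5
nordic	MPD	ML NOS	0	0	0
faroe	OTHER	L NOS	7	2	5
faroe	OTHER	MH	2	0	2
nordic	OTHER	L NOS	1	1	0
nordic	OTHER	MH	0	0	0
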