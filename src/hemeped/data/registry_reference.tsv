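group	abbrev	percent
LPD	HL	6
LPD	FL	12
LPD	MCL	<1
LPD	DLBCL	25
LPD	TNHL	2
LPD	MONOC	2
LPD	NHL NOS	6
LPD	WA	3
LPD	MM	14
LPD	ALL	4
LPD	CLL	22
LPD	PLL	1
LPD	HCL	1
LPD	LGTCL	<1
LPD	MGUS	2
MPD	AML	70
MPD	CML	15
MPD	PV	5
MPD	MDS	5
MPD	MF	5
MPD	ET	<1
MPD	ML NOS	<1
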