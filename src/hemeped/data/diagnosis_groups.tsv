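icd10	label	abbrev	group
C81	Hodgkin's lymphoma	HL	LPD
C82	Follicular lymphoma	FL	LPD
C82.7	Mantle cell lymphoma	MCL	LPD
C83.3	Diffuse large B-cell lymphoma	DLBCL	LPD
C84	Peripheral T-cell lymphoma	TNHL	LPD
C85.7	Monocytoid B-cell lymphoma	MONOC	LPD
C85.9	Non-Hodgkin lymphoma NOS	NHL NOS	LPD
C88	Waldenstrom's disease	WA	LPD
C90	Multiple myeloma	MM	LPD
C91.0	Acute lymphoblastic leukemia	ALL	LPD
C91.1	Chronic lymphocytic leukemia	CLL	LPD
C91.3	Prolymphocytic leukemia	PLL	LPD
C91.4	Hairy cell leukemia	HCL	LPD
C91.7	Large granular T-cell leukemia	LGTCL	LPD
D47.2	Monoclonal gammopathy	MGUS	LPD
C92.0	Acute myeloblastic leukemia	AML	MPD
C92.2	Acute myeloblastic leukemia	AML	MPD
C92.1	Chronic myeloid leukemia	CML	MPD
D45	Polycythemia vera	PV	MPD
D46	Myelodysplasia	MDS	MPD
D47.1	Myelofibrosis	MF	MPD
D47.3	Essential thrombocytosis	ET	MPD
C92.9	Myeloid leukemia uncertain	ML NOS	MPD
C95.9	Leukemia uncertain	L NOS	OTHER
C96.1	Malignant histiocytosis	MH	OTHER
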