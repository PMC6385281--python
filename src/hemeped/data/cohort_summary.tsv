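cohort	group	printed_ratio	onset_median	onset_median_males	onset_median_females
faroe	LPD	1.5	61	58	64
nordic	LPD	1.3	67	65	69
faroe	MPD	1.5	54	49	60
nordic	MPD	1.2	63	59	68
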