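variable	Healthy	AllrgRhin	AsmNoEx	AsmEx
participants	9	7	23	11
female	7	3	18	10
atopic	1	7	18	8
white	8	5	13	9
african_american	0	1	4	1
hispanic	0	0	3	0
other_ethnicity	1	1	3	1
inhaled_corticosteroids	0	0	6	3
ics_plus_laba	0	0	2	1
nasal_steroids	0	0	6	3
virus_rhinovirus	5	1	9	3
virus_rsv	0	0	2	1
virus_coronavirus	1	1	2	2
virus_influenza_a	0	1	1	0
virus_parainfluenza	0	1	0	0
virus_none_detected	3	3	9	5
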