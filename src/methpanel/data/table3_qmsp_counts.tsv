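series	gene	subtype	n_positive	n_total
test	DSP	BL	1	6
test	DSP	DLBCL_ABC	4	10
test	DSP	DLBCL_GCB	4	10
test	DSP	FL	1	10
test	FZD8	BL	6	6
test	FZD8	DLBCL_ABC	7	10
test	FZD8	DLBCL_GCB	4	10
test	FZD8	FL	7	10
test	KCNH2	BL	3	6
test	KCNH2	DLBCL_ABC	1	10
test	KCNH2	DLBCL_GCB	1	10
test	KCNH2	FL	3	10
test	KLF9	BL	0	7
test	KLF9	DLBCL_ABC	3	10
test	KLF9	DLBCL_GCB	1	10
test	KLF9	FL	0	10
test	MTSS1	BL	2	7
test	MTSS1	DLBCL_ABC	3	10
test	MTSS1	DLBCL_GCB	1	10
test	MTSS1	FL	1	10
test	NR4A2	BL	1	7
test	NR4A2	DLBCL_ABC	3	10
test	NR4A2	DLBCL_GCB	4	10
test	NR4A2	FL	0	10
test	PPP1R14A	BL	4	6
test	PPP1R14A	DLBCL_ABC	9	10
test	PPP1R14A	DLBCL_GCB	8	10
test	PPP1R14A	FL	7	10
test	panel	BL	6	6
test	panel	DLBCL_ABC	10	10
test	panel	DLBCL_GCB	8	10
test	panel	FL	10	10
test	panel	healthy_control	0	10
validation	DSP	DLBCL_ABC	3	8
validation	DSP	DLBCL_GCB	3	7
validation	DSP	FL	1	4
validation	DSP	PMBL	3	6
validation	FZD8	DLBCL_ABC	6	8
validation	FZD8	DLBCL_GCB	3	7
validation	FZD8	FL	2	4
validation	FZD8	PMBL	4	6
validation	KCNH2	DLBCL_ABC	2	8
validation	KCNH2	DLBCL_GCB	5	7
validation	KCNH2	FL	1	4
validation	KCNH2	PMBL	2	6
validation	PPP1R14A	DLBCL_ABC	6	8
validation	PPP1R14A	DLBCL_GCB	5	7
validation	PPP1R14A	FL	3	4
validation	PPP1R14A	PMBL	1	6
validation	panel	DLBCL_ABC	7	8
validation	panel	DLBCL_GCB	6	7
validation	panel	FL	3	4
validation	panel	PMBL	4	6
validation	panel	healthy_control	0	42
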