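pair_id	variant	passenger_notation	guide_notation	ic50_nM	tm_C	target
siSER-1	parent	ACCAGCGGCCUCUGGACCAdTdT	UGGUCCAGAGGCCGCUGGUdTdT	4.4	75.5	SERPINA6
siSER-1	modified	accaGfcGfGfCfcucuggaccadTdT	uGfgucCfagaggccGfcUfggudTdT	>100	86.7	SERPINA6
siSER-2	parent	CUCCCCUGUGAGCAUCUCAdTdT	UGAGAUGCUCACAGGGGAGdTdT	0.11	68.5	SERPINA6
siSER-2	modified	cuccCfcUfGfUfgagcaucucadTdT	uGfagaUfgcucacaGfgGfgagdTdT	27.2	78.5	SERPINA6
siSER-3	parent	CCCAGCUUCUCCAGGGCCUdTdT	AGGCCCUGGAGAAGCUGGGdTdT	0.33	74	SERPINA6
siSER-3	modified	cccaGfcUfUfCfuccagggccudTdT	aGfgccCfuggagaaGfcUfgggdTdT	>100	86.1	SERPINA6
siSER-4	parent	UUGCUGGAGUCAUUCUCAAdTdT	UUGAGAAUGACUCCAGCAAdTdT	0.032	59.5	SERPINA6
siSER-4	modified	uugcUfgGfAfGfucauucucaadTdT	uUfgagAfaugacucCfaGfcaadTdT	0.027	69.7	SERPINA6
siSER-5	parent	AGACAUCAAGCACUACUAUdTdT	AUAGUAGUGCUUGAUGUCUdTdT	0.2	56	SERPINA6
siSER-5	modified	agacAfuCfAfAfgcacuacuaudTdT	aUfaguAfgugcuugAfuGfucudTdT	0.23	66.3	SERPINA6
siSER-6	parent	UCCCCUGCCAGCUGGUGCAdTdT	UGCACCAGCUGGCAGGGGAdTdT	2.74	76	SERPINA6
siSER-6	modified	ucccCfuGfCfCfagcuggugcadTdT	uGfcacCfagcuggcAfgGfggadTdT	>100	87.7	SERPINA6
siSER-7	parent	AGGUCACCAUCUCUGGAGUdTdT	ACUCCAGAGAUGGUGACCUdTdT	0.56	65.1	SERPINA6
siSER-7	modified	agguCfaCfCfAfucucuggagudTdT	aCfuccAfgagauggUfgAfccudTdT	>100	78.1	SERPINA6
siSER-8	parent	UCACCUGGAGCAGCCUUUUdTdT	AAAAGGCUGCUCCAGGUGAdTdT	1.3	67.1	SERPINA6
siSER-8	modified	ucacCfuGfGfAfgcagccuuuudTdT	aAfaagGfcugcuccAfgGfugadTdT	0.15	77.6	SERPINA6
siSER-9	parent	CUGACUUUGGGAACCAGGAdTdT	UCCUGGUUCCCAAAGUCAGdTdT	0.16	63.2	SERPINA6
siSER-9	modified	cugaCfuUfUfGfggaaccaggadTdT	uCfcugGfuucccaaAfgUfcagdTdT	>100	73.7	SERPINA6
siSER-10	parent	AAGUUCUUCUCCCUCCAAAdTdT	UUUGGAGGGAGAAGAACUUdTdT	0.001	61.3	SERPINA6
siSER-10	modified	aaguUfcUfUfCfucccuccaaadTdT	uUfuggAfgggagaaGfaAfcuudTdT	0.004	71.3	SERPINA6
siSER-11	parent	ACUUUAGGCAUCUUUUAAUdTdT	AUUAAAAGAUGCCUAAAGUdTdT	0.0007	46.3	SERPINA6
siSER-11	modified	acuuUfaGfGfCfaucuuuuaaudTdT	aUfuaaAfagaugccUfaAfagudTdT	0.0001	56.1	SERPINA6
siAGT-1	parent	CCUGGCUGCAGGUGACCGAdTdT	UCGGUCACCUGCAGCCAGGdTdT	0.04	72.9	AGT
siAGT-1	modified	ccugGfcUfGfCfaggugaccgadTdT	uCfgguCfaccugcaGfcCfaggdTdT	>100	84.5	AGT
siAGT-2	parent	AGCAAUGACCGCAUCAGGAdTdT	UCCUGAUGCGGUCAUUGCUdTdT	0.13	64	AGT
siAGT-2	modified	agcaAfuGfAfCfcgcaucaggadTdT	uCfcugAfugcggucAfuUfgcudTdT	4.9	74.1	AGT
siAGT-3	parent	CAAAAAUUGGGUUUUAAAAdTdT	UUUUAAAACCCAAUUUUUGdTdT	0.0004	39	AGT
siAGT-3	modified	caaaAfaUfUfGfgguuuuaaaadTdT	uUfuuaAfaacccaaUfuUfuugdTdT	0.022	47.2	AGT
siAGT-4	parent	GGGUGGGGAGGCAAGAACAdTdT	UGUUCUUGCCUCCCCACCCdTdT	0.01	73.5	AGT
siAGT-4	modified	ggguGfgGfGfAfggcaagaacadTdT	uGfuucUfugccuccCfcAfcccdTdT	0.21	83.8	AGT
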