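breed	chrom	start_bp	end_bp	n_snps	fix_pct	genes
BAR	2	123468577	123637801	24	41.67	FSIP2
BAR	9	77728073	77935397	18	38.89	VPS13B;ENSOARG00020009652
BAR	13	49229596	49594105	43	47.67	-
BAR	18	54247130	54348566	19	39.58	CATSPERB;TC2N
NOT	10	42419945	42678764	25	64.58	ENSOARG00020035296
NOT	13	49785151	49978019	19	39.58	-
NOT	18	54247130	54348566	19	43.75	CATSPERB;TC2N
NOT	22	22332864	22519184	24	41.15	KCNIP2;ARMH3
NOT	23	41944403	42054238	20	33.33	NDUFV2;ANKRD12;ENSOARG00020030516
SAR	2	51458838	51550541	12	30.00	ZCCHC7
SAR	2	123468577	123637801	24	38.13	FSIP2
SAR	10	42441586	42678764	23	30.00	ENSOARG00020035296
VDB	2	113906067	114026175	15	30.15	NIPA2;CYFIP1;ENSOARG00020028055
VDB	3	171435795	171532877	14	30.15	WASHC3;NUP37;PARPBP
VDB	9	77754258	77935397	15	30.88	VPS13B;ENSOARG00020009652
VDB	10	42441586	42678764	23	39.58	ENSOARG00020035296
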