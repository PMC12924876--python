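breed	chrom	start_bp	end_bp	n_snps	fix_pct	genes
BAR	6	36713446	39067495	291	99.96	HERC3;NAP1L5;PYURF;ENSOARG00020023567;HERC6;PPM1K;ABCG2;PKD2;SPP1;MEPE;IBSP;LAP3;FAM184B;DCAF16;NCAPG;LCORL;ENSOARG00020029550;ENSOARG00020032248
BAR	10	42322026	43925475	175	99.96	ENSOARG00020035296;ENSOARG00020035750
NOT	2	82601893	85428011	525	75.74	ENSOARG00020028478;ENSOARG00020033455;ENSOARG00020032799;NFIB;ENSOARG00020040248;ZDHHC21;ENSOARG00020030911;ENSOARG00020034846;CER1;FREM1;ENSOARG00020034967;ENSOARG00020037234;TTC39B;ENSOARG00020040142;SNAPC3;PSIP1;ENSOARG00020037607;CCDC171;ENSOARG00020032888;BNC2
SAR	3	106277679	106854930	23	25.71	FBLN7;ZC3H8;ENSOARG00020035986;ZC3H6;ENSOARG00020036183;ENSOARG00020026712
SAR	10	37074391	38323145	130	27.74	ENSOARG00020030504;ENSOARG00020035296
SAR	10	42322026	43393956	108	27.19	ENSOARG00020035296;ENSOARG00020035750
SAR	19	35944655	36074417	21	25.82	MAGI1;ENSOARG00020033686
SAR	19	36582133	37265170	148	26.77	ENSOARG00020012610;ENSOARG00020030976;ENSOARG00020038383;ENSOARG00020030184;ENSOARG00020026999;ADAMTS9;ENSOARG00020030753;PRICKLE2
SAR	19	37986438	39058275	214	25.77	SYNPR;ENSOARG00020032605;CADPS;FEZF2
VDB	4	93280238	94696523	307	21.93	ENSOARG00020039523;ZNF800;GCC1;ARF5;FSCN3;PAX4;SND1;LRRC4;ENSOARG00020035180;ENSOARG00020037327;ENSOARG00020030512;ENSOARG00020036546;ENSOARG00020029720;MIR129-1;ENSOARG00020040526;LEP;ENSOARG00020032751;RBM28;PRRT4;ENSOARG00020027789;IMPDH1;HILPDA;GARIN1A;CALU;OPN1SW;CCDC136;FLNC;ATP6V1F;ATP6V1FNB;KCP;IRF5;TNPO3
VDB	10	37396295	38863812	114	22.42	ENSOARG00020030504
VDB	10	42322720	43393956	111	22.69	ENSOARG00020035296;ENSOARG00020035750
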