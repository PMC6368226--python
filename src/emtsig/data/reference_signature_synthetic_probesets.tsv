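probeset_id	gene_symbol	direction	provenance
PS_ACTN1_1	ACTN1	1	algorithmic
PS_ACTN1_2	ACTN1	1	algorithmic
PS_ADGRF4_1	ADGRF4	-1	algorithmic
PS_ADGRF4_2	ADGRF4	-1	algorithmic
PS_AFAP1L2_1	AFAP1L2	1	algorithmic
PS_AFAP1L2_2	AFAP1L2	1	algorithmic
PS_ANKLE2_1	ANKLE2	-1	algorithmic
PS_ANKLE2_2	ANKLE2	-1	algorithmic
PS_ARHGEF18_1	ARHGEF18	1	algorithmic
PS_ARHGEF18_2	ARHGEF18	1	algorithmic
PS_ARHGEF40_1	ARHGEF40	1	algorithmic
PS_ARHGEF40_2	ARHGEF40	1	algorithmic
PS_BEAN1_1	BEAN1	-1	algorithmic
PS_BEAN1_2	BEAN1	-1	algorithmic
PS_BICDL1_1	BICDL1	-1	algorithmic
PS_BICDL1_2	BICDL1	-1	algorithmic
PS_BMP1_1	BMP1	1	algorithmic
PS_BMP1_2	BMP1	1	algorithmic
PS_CALD1_1	CALD1	1	algorithmic
PS_CALD1_2	CALD1	1	algorithmic
PS_CERCAM_1	CERCAM	1	algorithmic
PS_CERCAM_2	CERCAM	1	algorithmic
PS_CHST3_1	CHST3	1	algorithmic
PS_CHST3_2	CHST3	1	algorithmic
PS_CMTM3_1	CMTM3	1	algorithmic
PS_CMTM3_2	CMTM3	1	algorithmic
PS_COL1A1_1	COL1A1	1	algorithmic
PS_COL1A1_2	COL1A1	1	algorithmic
PS_COL7A1_1	COL7A1	1	algorithmic
PS_COL7A1_2	COL7A1	1	algorithmic
PS_DBN1_1	DBN1	1	algorithmic
PS_DBN1_2	DBN1	1	algorithmic
PS_DEPTOR_1	DEPTOR	-1	algorithmic
PS_DEPTOR_2	DEPTOR	-1	algorithmic
PS_EEPD1_1	EEPD1	-1	algorithmic
PS_EEPD1_2	EEPD1	-1	algorithmic
PS_EHF_1	EHF	-1	algorithmic
PS_EHF_2	EHF	-1	algorithmic
PS_EPB41L5_1	EPB41L5	-1	algorithmic
PS_EPB41L5_2	EPB41L5	-1	algorithmic
PS_EPHB2_1	EPHB2	1	algorithmic
PS_EPHB2_2	EPHB2	1	algorithmic
PS_EXOC6_1	EXOC6	-1	algorithmic
PS_EXOC6_2	EXOC6	-1	algorithmic
PS_FLNA_1	FLNA	1	algorithmic
PS_FLNA_2	FLNA	1	algorithmic
PS_FRMD6_1	FRMD6	-1	algorithmic
PS_FRMD6_2	FRMD6	-1	algorithmic
PS_GADD45B_1	GADD45B	1	algorithmic
PS_GADD45B_2	GADD45B	1	algorithmic
PS_GALNT2_1	GALNT2	1	algorithmic
PS_GALNT2_2	GALNT2	1	algorithmic
PS_IL11_1	IL11	1	algorithmic
PS_IL11_2	IL11	1	algorithmic
PS_ITGA5_1	ITGA5	1	algorithmic
PS_ITGA5_2	ITGA5	1	algorithmic
PS_JUNB_1	JUNB	1	algorithmic
PS_KCTD11_1	KCTD11	-1	algorithmic
PS_KLF7_1	KLF7	1	algorithmic
PS_LAMC2_1	LAMC2	1	algorithmic
PS_LTBP1_1	LTBP1	1	algorithmic
PS_LTBP3_1	LTBP3	1	algorithmic
PS_LTBP4_1	LTBP4	1	algorithmic
PS_MAF_1	MAF	1	algorithmic
PS_MAPRE2_1	MAPRE2	-1	algorithmic
PS_MBOAT2_1	MBOAT2	-1	algorithmic
PS_METRNL_1	METRNL	-1	algorithmic
PS_MLXIP_1	MLXIP	-1	algorithmic
PS_MUC5AC_1	MUC5AC	-1	algorithmic
PS_MUC5B_1	MUC5B	-1	algorithmic
PS_NAV1_1	NAV1	1	algorithmic
PS_NCOR2_1	NCOR2	1	algorithmic
PS_NKAIN4_1	NKAIN4	-1	algorithmic
PS_PDLIM7_1	PDLIM7	1	algorithmic
PS_PEA15_1	PEA15	1	algorithmic
PS_PIK3CD_1	PIK3CD	1	algorithmic
PS_PLAUR_1	PLAUR	1	algorithmic
PS_PLEK2_1	PLEK2	1	algorithmic
PS_PMEPA1_1	PMEPA1	1	algorithmic
PS_PPP1R13L_1	PPP1R13L	1	algorithmic
PS_PPP1R18_1	PPP1R18	1	algorithmic
PS_PTRF_1	PTRF	1	algorithmic
PS_PXDC1_1	PXDC1	1	algorithmic
PS_PXN-AS1_1	PXN-AS1	-1	algorithmic
PS_RHOD_1	RHOD	1	algorithmic
PS_SAMD4A_1	SAMD4A	1	algorithmic
PS_SERPINE1_1	SERPINE1	1	algorithmic
PS_SHANK3_1	SHANK3	1	algorithmic
PS_SKIL_1	SKIL	1	algorithmic
PS_SMAD7_1	SMAD7	1	algorithmic
PS_SNAI1_1	SNAI1	1	algorithmic
PS_TBC1D30_1	TBC1D30	-1	algorithmic
PS_TGFB1I1_1	TGFB1I1	1	algorithmic
PS_TGFBR1_1	TGFBR1	1	algorithmic
PS_THRB_1	THRB	-1	algorithmic
PS_TIMP2_1	TIMP2	1	algorithmic
PS_TMC5_1	TMC5	-1	algorithmic
PS_TP53I3_1	TP53I3	-1	algorithmic
PS_TPM1_1	TPM1	1	algorithmic
PS_TRIO_1	TRIO	1	algorithmic
PS_TRMT10A_1	TRMT10A	-1	algorithmic
PS_TSPAN2_1	TSPAN2	1	algorithmic
PS_VCAN_1	VCAN	1	algorithmic
PS_WNT7A_1	WNT7A	-1	algorithmic
PS_ZFP36L1_1	ZFP36L1	1	algorithmic
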