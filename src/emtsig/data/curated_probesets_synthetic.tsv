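probeset_id	gene_symbol	direction
PS_DDR1_1	DDR1	-1
PS_DDR1_2	DDR1	-1
PS_LTBP1_1	LTBP1	1
PS_PDGFB_1	PDGFB	1
PS_SMURF1_1	SMURF1	1
PS_SNAI1_1	SNAI1	1
PS_TGFBR1_1	TGFBR1	1
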