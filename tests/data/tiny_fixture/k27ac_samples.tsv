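sample	stage	genotype	replicate
K27ac_D35_WT_r1	D35	WT	1
K27ac_D35_WT_r2	D35	WT	2
K27ac_D35_WT_r3	D35	WT	3
K27ac_D35_WT_r4	D35	WT	4
K27ac_D35_HET_r1	D35	HET	1
K27ac_D35_HET_r2	D35	HET	2
K27ac_D35_HET_r3	D35	HET	3
K27ac_D35_HET_r4	D35	HET	4
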